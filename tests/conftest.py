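import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cacyreus import (CountData, LandscapeConfig, LandscapeGrid,
                      default_truth, make_landscape, simulate_counts,
                      stratified_design)


@pytest.fixture(scope="session")
def small_grid() -> LandscapeGrid:
    return make_landscape(LandscapeConfig(n_rows=20, n_cols=20), seed=42)


@pytest.fixture(scope="session")
def study_grid() -> LandscapeGrid:
    """A grid at roughly the scale of the real survey valley."""
    return make_landscape(LandscapeConfig(n_rows=30, n_cols=30), seed=7)


@pytest.fixture(scope="session")
def study_design(study_grid):
    return stratified_design(study_grid, n_per_band=25, visits=3, seed=1)


@pytest.fixture(scope="session")
def study_counts(study_grid, study_design) -> CountData:
    return simulate_counts(study_grid, study_design, default_truth(), seed=3)


@pytest.fixture(scope="session")
def study_counts_scaled(study_counts) -> CountData:
    return study_counts.standardize(["bio01", "pel_abu", "pel_neigh",
                                     "pel_ava"])


def flat_grid(n_rows: int, n_cols: int, **columns) -> LandscapeGrid:
    """Hand-built grid with constant default covariates (test helper)."""
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols),
                             indexing="ij")
    n = n_rows * n_cols
    base = {
        "cell_id": [f"c{r:03d}_{c:03d}" for r, c in
                    zip(rows.ravel(), cols.ravel())],
        "row": rows.ravel(), "col": cols.ravel(),
        "elevation": np.full(n, 1000.0), "bio01": np.full(n, 6.0),
        "bio04": np.full(n, 6000.0), "pel_abu": np.zeros(n, dtype=int),
        "pel_neigh": np.zeros(n), "wood": np.full(n, 0.3),
        "eco": np.full(n, 0.2), "grass": np.full(n, 0.3),
        "municipality": np.repeat("M01", n), "urban": np.ones(n, dtype=bool),
    }
    base.update({k: np.asarray(v) for k, v in columns.items()})
    grid = LandscapeGrid(cells=pd.DataFrame(base), n_rows=n_rows,
                         n_cols=n_cols)
    if "pel_neigh" not in columns:
        grid.refresh_pel_neigh()
    return grid
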