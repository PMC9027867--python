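"""CSV readers/writers for grids, counts and presence points.

CSV is the canonical interchange format; every table carries an explicit
documented header and round-trips losslessly.  Unknown grid columns are
preserved as opaque attributes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .countdata import CountData
from .landscape import GRID_COLUMNS, LandscapeGrid


def write_grid(grid: LandscapeGrid, path: str | Path) -> None:
    cols = GRID_COLUMNS + [c for c in grid.cells.columns if c not in GRID_COLUMNS]
    grid.cells[cols].to_csv(path, index=False)


def read_grid(path: str | Path) -> LandscapeGrid:
    """Read a grid CSV; errors name any missing mandatory column."""
    df = pd.read_csv(path)
    missing = [c for c in GRID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"grid file {path} lacks columns: {missing}")
    pel = df["pel_abu"].to_numpy()
    if not np.allclose(pel, np.round(pel)):
        raise ValueError("pel_abu must be integer-valued")
    df["pel_abu"] = df["pel_abu"].astype(int)
    df["urban"] = df["urban"].astype(bool)
    return LandscapeGrid(cells=df, n_rows=int(df["row"].max()) + 1,
                         n_cols=int(df["col"].max()) + 1)


def write_counts(data: CountData, path: str | Path) -> None:
    data.to_frame().to_csv(path, index=False)


def read_counts(path: str | Path,
                site_covariate_names: list[str] | None = None) -> CountData:
    """Read a wide counts CSV: site_id, visit_1..visit_J, covariates."""
    df = pd.read_csv(path)
    if "site_id" not in df.columns:
        raise ValueError(f"counts file {path} lacks column 'site_id'")
    visit_cols = sorted([c for c in df.columns if c.startswith("visit_")],
                        key=lambda c: int(c.split("_")[1]))
    if not visit_cols:
        raise ValueError(f"counts file {path} has no visit_* columns")
    if "pel_ava" not in df.columns:
        raise ValueError(f"counts file {path} lacks column 'pel_ava'")
    df = df.set_index("site_id")
    y = df[visit_cols].astype(float)
    if site_covariate_names is None:
        site_covariate_names = [c for c in df.columns
                                if c not in visit_cols + ["pel_ava"]]
    return CountData(y=y, site_covariates=df[site_covariate_names],
                     obs_covariates=df[["pel_ava"]])


def write_points(points: pd.DataFrame, path: str | Path) -> None:
    points[["point_id", "cell_id", "x", "y"]].to_csv(path, index=False)


def read_points(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("point_id", "cell_id", "x", "y")
               if c not in df.columns]
    if missing:
        raise ValueError(f"points file {path} lacks columns: {missing}")
    return df
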