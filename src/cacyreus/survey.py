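"""Survey design and generative simulation of egg counts and presences.

The standardized protocol stratifies the landscape into altitudinal bands,
samples cells uniformly at random within each band and revisits each cell
several times.  Counts are generated from the same hierarchical process the
abundance model assumes — latent egg abundance from a (possibly
zero-inflated) count mixture, binomial thinning by imperfect detection —
so simulated data are a generative twin of the fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .countdata import CountData
from .landscape import LandscapeGrid

#: the study's altitudinal bands (m a.s.l.)
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (500.0, 1000.0), (1000.0, 1500.0), (1500.0, 2000.0),
)


@dataclass
class TruthParams:
    """Generative parameters of the egg-count process.

    ``beta`` are abundance coefficients on the log scale, ``alpha``
    detection coefficients on the logit scale; both apply to covariates
    standardized over the sampled cells.  Keys are covariate names,
    ``"intercept"`` for intercepts and ``"a:b"`` for interactions.
    ``psi`` is the zero-inflation probability (ZIP only); ``theta`` the
    negative-binomial dispersion (NB only; variance lam + lam^2/theta).
    """

    beta: dict[str, float]
    alpha: dict[str, float]
    psi: float = 0.0
    theta: float = 1.0
    mixture: str = "P"

    def __post_init__(self) -> None:
        if self.mixture not in {"P", "NB", "ZIP"}:
            raise ValueError("mixture must be one of P, NB, ZIP")
        if self.mixture == "ZIP" and not 0.0 <= self.psi <= 1.0:
            raise ValueError("psi must lie in [0, 1]")
        if self.mixture == "NB" and self.theta <= 0:
            raise ValueError("theta must be positive")


def default_truth(mixture: str = "ZIP", psi: float = 0.5) -> TruthParams:
    """Default generative parameters of the synthetic study.

    Strong positive host-plant and temperature effects with a positive
    synergistic interaction, a negative effect of neighbouring host-plant
    availability, and low per-visit detection that improves with the
    number of accessible pots.
    """
    return TruthParams(
        beta={"intercept": 3.095, "bio01": 0.446, "pel_abu": 0.320,
              "pel_neigh": -0.343, "pel_abu:bio01": 0.592},
        alpha={"intercept": -2.632, "pel_ava": 0.399},
        psi=psi if mixture == "ZIP" else 0.0,
        mixture=mixture,
    )


@dataclass
class SurveyDesign:
    """A stratified random survey: which cells, which band, how many visits."""

    bands: list[tuple[float, float]]
    cells_per_band: int
    visits_per_cell: int
    selected_cells: pd.DataFrame  # columns: cell_id, band
    seed: int

    @property
    def n_sites(self) -> int:
        return len(self.selected_cells)

    @property
    def n_site_visits(self) -> int:
        return self.n_sites * self.visits_per_cell

    def validate(self, grid: LandscapeGrid) -> None:
        merged = self.selected_cells.merge(grid.cells[["cell_id", "elevation"]],
                                           on="cell_id", how="left")
        for b, (lo, hi) in enumerate(self.bands):
            sub = merged[merged["band"] == b]
            if len(sub) != self.cells_per_band:
                raise ValueError(f"band {b} has {len(sub)} cells, "
                                 f"expected {self.cells_per_band}")
            if not ((sub["elevation"] >= lo) & (sub["elevation"] <= hi)).all():
                raise ValueError(f"band {b} contains cells outside [{lo}, {hi}] m")


def stratified_design(grid: LandscapeGrid,
                      bands: list[tuple[float, float]] | None = None,
                      n_per_band: int = 25,
                      visits: int = 3,
                      seed: int | np.random.Generator = 0,
                      eligibility: str | None = None) -> SurveyDesign:
    """Stratified random sampling of survey cells within altitudinal bands.

    ``eligibility`` restricts the candidate pool: ``None`` admits every
    cell; ``"open"`` emulates the protocol's open-area/village filter
    (cells with under 75% woodland cover, or urban cells).
    """
    bands = list(bands) if bands is not None else list(DEFAULT_BANDS)
    rng = np.random.default_rng(seed)
    df = grid.cells
    if eligibility is None:
        eligible = pd.Series(True, index=df.index)
    elif eligibility == "open":
        eligible = (df["wood"] < 0.75) | df["urban"].astype(bool)
    else:
        raise ValueError(f"unknown eligibility rule {eligibility!r}")

    picks = []
    for b, (lo, hi) in enumerate(bands):
        pool = df[eligible & (df["elevation"] >= lo) & (df["elevation"] <= hi)]
        if len(pool) < n_per_band:
            raise ValueError(
                f"band {b} ({lo:g}-{hi:g} m) has only {len(pool)} eligible "
                f"cells, need {n_per_band}")
        chosen = rng.choice(pool["cell_id"].to_numpy(), size=n_per_band,
                            replace=False)
        picks.append(pd.DataFrame({"cell_id": chosen, "band": b}))
    selected = pd.concat(picks, ignore_index=True)
    seed_int = int(seed) if not isinstance(seed, np.random.Generator) else -1
    return SurveyDesign(bands=bands, cells_per_band=n_per_band,
                        visits_per_cell=visits, selected_cells=selected,
                        seed=seed_int)


def _standardized_design_matrix(covs: pd.DataFrame, terms: dict[str, float],
                                means_sds: dict[str, tuple[float, float]]):
    """Linear predictor of ``terms`` over standardized columns of ``covs``."""
    eta = np.zeros(len(covs))
    for name, coef in terms.items():
        if name == "intercept":
            eta += coef
            continue
        parts = name.split(":")
        col = np.ones(len(covs))
        for part in parts:
            mean, sd = means_sds[part]
            col = col * (covs[part].to_numpy(float) - mean) / sd
        eta += coef * col
    return eta


def _scaling(covs: pd.DataFrame, names: set[str]) -> dict[str, tuple[float, float]]:
    out = {}
    for name in names:
        col = covs[name].to_numpy(float)
        mean, sd = float(col.mean()), float(col.std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"covariate {name!r} constant over the cells used")
        out[name] = (mean, sd)
    return out


def _main_effects(terms: dict[str, float]) -> set[str]:
    names: set[str] = set()
    for key in terms:
        if key == "intercept":
            continue
        names.update(key.split(":"))
    return names


def _draw_latent(rng: np.random.Generator, lam: np.ndarray,
                 truth: TruthParams) -> np.ndarray:
    if truth.mixture == "P":
        return rng.poisson(lam)
    if truth.mixture == "NB":
        return rng.negative_binomial(truth.theta, truth.theta / (truth.theta + lam))
    zero = rng.random(lam.shape) < truth.psi
    return np.where(zero, 0, rng.poisson(lam))


def simulate_counts(grid: LandscapeGrid, design: SurveyDesign,
                    truth: TruthParams, seed: int | np.random.Generator = 0,
                    access_beta: tuple[float, float] = (2.0, 2.0)) -> CountData:
    """Simulate repeated egg counts at the design's cells.

    Covariates are standardized internally over the design cells before the
    truth coefficients are applied; the returned :class:`CountData` carries
    the raw covariates (an explicit :meth:`CountData.standardize` at fit
    time reproduces the same scaling).  ``pel_ava``, the detection
    covariate, is a binomial thinning of each site's pot count
    (accessibility ``pel_access``), constant across visits.
    """
    rng = np.random.default_rng(seed)
    site_ids = design.selected_cells["cell_id"]
    covs = (grid.cells.set_index("cell_id")
            .loc[site_ids]
            .reset_index())

    access = rng.beta(*access_beta, size=len(covs))
    pel_ava = rng.binomial(covs["pel_abu"].to_numpy(int), access).astype(float)
    covs = covs.assign(pel_ava=pel_ava)

    names = _main_effects(truth.beta) | _main_effects(truth.alpha)
    scaling = _scaling(covs, names)
    eta_ab = _standardized_design_matrix(covs, truth.beta, scaling)
    eta_det = _standardized_design_matrix(covs, truth.alpha, scaling)
    if not (np.isfinite(eta_ab).all() and np.isfinite(eta_det).all()):
        raise ValueError("non-finite linear predictor")
    lam = np.exp(eta_ab)
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-eta_det))
    p = np.clip(p, 0.0, 1.0)

    n_latent = _draw_latent(rng, lam, truth)
    J = design.visits_per_cell
    y = rng.binomial(n_latent[:, None], p[:, None], size=(len(covs), J))

    y_df = pd.DataFrame(y, index=site_ids.to_numpy(),
                        columns=[f"visit_{j + 1}" for j in range(J)], dtype=float)
    site_cov_cols = ["elevation", "bio01", "bio04", "pel_abu", "pel_neigh",
                     "wood", "eco", "grass"]
    site_covs = covs[site_cov_cols].set_index(site_ids.to_numpy())
    obs_covs = pd.DataFrame({"pel_ava": pel_ava}, index=site_ids.to_numpy())
    return CountData(y=y_df, site_covariates=site_covs, obs_covariates=obs_covs)


def simulate_opportunistic(grid: LandscapeGrid, truth: TruthParams,
                           n_points: int = 138, bias_strength: float = 1.0,
                           seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Spatially biased presence-only points.

    Cells are sampled (with replacement) with probability proportional to
    expected egg abundance times an accessibility bias factor
    ``exp(bias_strength * access)`` where ``access`` is high in urban and
    low-elevation cells, emulating opportunistic recording near roads and
    villages.  Returns a table ``point_id, cell_id, x, y`` (metric
    coordinates with within-cell jitter); no absences.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    covs = grid.cells
    names = _main_effects(truth.beta)
    scaling = _scaling(covs, names)
    eta = _standardized_design_matrix(covs, truth.beta, scaling)
    expected = np.exp(eta)
    if truth.mixture == "ZIP":
        expected = (1.0 - truth.psi) * expected
    if not np.any(expected > 0):
        raise ValueError("expected abundance is zero everywhere")

    elev = covs["elevation"].to_numpy(float)
    elev01 = (elev - elev.min()) / max(elev.max() - elev.min(), 1e-12)
    access = covs["urban"].astype(bool).to_numpy() * 1.0 + (1.0 - elev01)
    weight = expected * np.exp(bias_strength * access)
    weight = weight / weight.sum()

    idx = rng.choice(len(covs), size=n_points, p=weight)
    centres = grid.cell_centres()[idx]
    jitter = rng.uniform(-0.5, 0.5, size=(n_points, 2)) * grid.resolution_m
    return pd.DataFrame({
        "point_id": [f"p{i:04d}" for i in range(n_points)],
        "cell_id": covs["cell_id"].to_numpy()[idx],
        "x": centres[:, 0] + jitter[:, 0],
        "y": centres[:, 1] + jitter[:, 1],
    })
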