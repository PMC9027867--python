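"""Synthetic alpine landscapes for host-plant-limited butterfly models.

The study system is a 250 m grid over an alpine valley: temperature falls
with elevation, the host plant (ornamental *Pelargonium* pots) is confined
to village (urban) cells on the valley floor and lower slopes, and land
cover is a mix of woodland, ecotone and grassland.  :func:`make_landscape`
generates grids with that structure; :class:`LandscapeGrid` is the common
substrate consumed by the survey simulator, both distribution models and
the scenario engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: resolution of the study grid in metres (fixed by the study design)
RESOLUTION_M = 250.0

#: mandatory columns of the grid table, in canonical order
GRID_COLUMNS = [
    "cell_id", "row", "col", "elevation", "bio01", "bio04",
    "pel_abu", "pel_neigh", "wood", "eco", "grass", "municipality", "urban",
]


class ConfigurationError(ValueError):
    """Raised when landscape parameters are inconsistent."""


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic landscape generator.

    Defaults emulate the study conditions: an elevation gradient spanning
    the three 500 m survey bands, a 6.5 degC/km lapse rate, villages (and
    hence host-plant pots) clustered at low elevation.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions (cells); must both be >= 3.
    elev_range
        (low, high) elevation in m a.s.l.; the gradient runs along rows.
    lapse_rate
        Temperature lapse in degC per km of elevation.
    t_sea_level
        Annual mean temperature (bio01, degC) extrapolated to 0 m.
    bio01_noise_sd
        Spatial noise on bio01 (degC).  The default 0 keeps bio01 a strict
        function of elevation.
    bio04_base, bio04_per_m, bio04_noise_sd
        Temperature seasonality (unitless index) intercept, elevation trend
        and noise.
    urban_fraction
        Target fraction of cells belonging to village patches.
    urban_max_elev
        Villages are only seeded below this elevation.
    village_elev_decay
        e-folding length (m) of the village seeding weight above the
        valley floor; larger values spread villages to higher elevations.
    village_size
        Mean number of cells per village patch.
    pot_mean
        Grid-wide mean pot count scale for pot-bearing urban cells.  The
        per-cell mean rises with elevation (the pot-richest squares sit in
        high tourist villages, as in the study area's census) and counts
        are Gamma-mixed Poisson draws kept >= 10.
    pot_prob
        Probability that an urban cell holds any pots.
    n_municipalities
        Number of contiguous municipality blocks the grid is split into.
    elev_noise_sd
        Random roughness added to the elevation ramp (m).
    """

    n_rows: int = 40
    n_cols: int = 40
    elev_range: tuple[float, float] = (500.0, 2000.0)
    lapse_rate: float = 6.5
    t_sea_level: float = 13.0
    bio01_noise_sd: float = 0.0
    bio04_base: float = 6000.0
    bio04_per_m: float = 0.2
    bio04_noise_sd: float = 160.0
    urban_fraction: float = 0.25
    urban_max_elev: float = 1950.0
    village_size: float = 5.0
    village_elev_decay: float = 1200.0
    pot_mean: float = 22.0
    pot_prob: float = 0.8
    n_municipalities: int = 8
    elev_noise_sd: float = 25.0

    def validate(self) -> None:
        if self.n_rows < 3 or self.n_cols < 3:
            raise ConfigurationError("grid must be at least 3x3")
        lo, hi = self.elev_range
        if not lo < hi:
            raise ConfigurationError("elevation range must satisfy low < high")
        if not 0.0 <= self.urban_fraction <= 1.0:
            raise ConfigurationError("urban_fraction must lie in [0, 1]")
        if self.pot_mean < 10.0:
            raise ConfigurationError("pot_mean must be >= 10")


@dataclass
class LandscapeGrid:
    """A rectangular 250 m grid of per-cell covariates.

    ``cells`` is a DataFrame with the columns in :data:`GRID_COLUMNS`
    (extra columns are preserved untouched).  Cell centres sit at
    ``(col + 0.5, row + 0.5) * resolution_m`` in metric coordinates.
    """

    cells: pd.DataFrame
    n_rows: int
    n_cols: int
    resolution_m: float = RESOLUTION_M

    def __post_init__(self) -> None:
        missing = [c for c in GRID_COLUMNS if c not in self.cells.columns]
        if missing:
            raise ConfigurationError(f"grid table lacks columns: {missing}")

    def __len__(self) -> int:
        return len(self.cells)

    def validate(self) -> None:
        """Check the structural invariants of the grid."""
        df = self.cells
        if df.duplicated(["row", "col"]).any():
            raise ConfigurationError("duplicate (row, col) indices")
        cover = df[["wood", "eco", "grass"]].sum(axis=1)
        if ((df[["wood", "eco", "grass"]] < -1e-12).any().any()
                or (cover > 1 + 1e-9).any()):
            raise ConfigurationError("wood+eco+grass must lie in [0, 1]")
        pel = df["pel_abu"].to_numpy()
        if (pel < 0).any() or not np.allclose(pel, np.round(pel)):
            raise ConfigurationError("pel_abu must be non-negative integers")
        if ((pel > 0) & ~df["urban"].astype(bool)).any():
            raise ConfigurationError("pel_abu > 0 outside urban cells")
        expected = self.neighbour_sum("pel_abu")
        if not np.allclose(df["pel_neigh"].to_numpy(), expected):
            raise ConfigurationError("pel_neigh does not match 8-neighbour sum")

    def to_array(self, column: str) -> np.ndarray:
        """Return a column as an (n_rows, n_cols) array (NaN off-grid)."""
        arr = np.full((self.n_rows, self.n_cols), np.nan)
        df = self.cells
        arr[df["row"].to_numpy(), df["col"].to_numpy()] = df[column].to_numpy(float)
        return arr

    def neighbour_sum(self, column: str) -> np.ndarray:
        """Sum of ``column`` over the 8-cell Moore neighbourhood.

        The focal cell is excluded; the window is truncated at grid edges.
        Returned in the row order of ``cells``.
        """
        arr = np.nan_to_num(self.to_array(column))
        padded = np.pad(arr, 1)
        total = np.zeros_like(arr)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                total += padded[1 + dr:1 + dr + self.n_rows,
                                1 + dc:1 + dc + self.n_cols]
        df = self.cells
        return total[df["row"].to_numpy(), df["col"].to_numpy()]

    def refresh_pel_neigh(self) -> None:
        """Recompute pel_neigh from pel_abu in place (idempotent)."""
        self.cells["pel_neigh"] = self.neighbour_sum("pel_abu")

    def cell_centres(self) -> np.ndarray:
        """Metric (x, y) coordinates of each cell centre, shape (n, 2)."""
        df = self.cells
        x = (df["col"].to_numpy(float) + 0.5) * self.resolution_m
        y = (df["row"].to_numpy(float) + 0.5) * self.resolution_m
        return np.column_stack([x, y])


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  sd: float, passes: int = 4) -> np.ndarray:
    """White noise smoothed by repeated 3x3 box filtering, rescaled to sd."""
    if sd == 0:
        return np.zeros(shape)
    z = rng.normal(size=shape)
    for _ in range(passes):
        padded = np.pad(z, 1, mode="edge")
        z = sum(padded[1 + dr:1 + dr + shape[0], 1 + dc:1 + dc + shape[1]]
                for dr in (-1, 0, 1) for dc in (-1, 0, 1)) / 9.0
    s = z.std()
    return z * (sd / s) if s > 0 else z


def make_landscape(config: LandscapeConfig | None = None,
                   seed: int | np.random.Generator = 0) -> LandscapeGrid:
    """Generate a synthetic valley landscape.

    Elevation ramps from ``elev_range[0]`` (valley floor, row 0) to
    ``elev_range[1]`` with mild roughness; bio01 follows the lapse rate;
    villages are grown as contiguous patches seeded preferentially at low
    elevation, and only village cells hold Pelargonium pots.  Deterministic
    for a fixed seed.
    """
    config = config or LandscapeConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    nr, nc = config.n_rows, config.n_cols
    lo, hi = config.elev_range

    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    ramp = rows / max(nr - 1, 1)
    tilt = 0.03 * cols / max(nc - 1, 1)  # slight cross-valley slope
    elevation = lo + (hi - lo) * np.clip(ramp + tilt, 0, 1)
    elevation += _smooth_noise(rng, (nr, nc), config.elev_noise_sd)
    elevation = np.clip(elevation, lo, hi)

    bio01 = (config.t_sea_level - config.lapse_rate * elevation / 1000.0
             + _smooth_noise(rng, (nr, nc), config.bio01_noise_sd))
    bio04 = (config.bio04_base + config.bio04_per_m * elevation
             + rng.normal(0, config.bio04_noise_sd, size=(nr, nc)))

    urban = _grow_villages(rng, elevation, config)

    pel_abu = np.zeros((nr, nc), dtype=int)
    has_pots = urban & (rng.random((nr, nc)) < config.pot_prob)
    n_pots = has_pots.sum()
    # per-cell mean rises with elevation: valley cells keep modest window
    # boxes, high tourist villages host the large flowered squares
    elev01 = (elevation - lo) / (hi - lo)
    m_cell = config.pot_mean * (0.5 + 1.5 * elev01[has_pots])
    # Gamma-mixed Poisson counts: most cells hold tens of pots, the
    # best-flowered squares a couple of hundred
    spread = rng.gamma(4.0, 0.25, size=n_pots)
    pel_abu[has_pots] = 10 + rng.poisson(m_cell * spread)

    # land cover: Dirichlet over (wood, eco, grass, other); woodland thins
    # above the treeline, villages keep a larger "other" share
    alpha = np.empty((nr * nc, 4))
    flat_elev = elevation.ravel()
    alpha[:, 0] = 2.0 * np.exp(-np.maximum(flat_elev - 1800.0, 0.0) / 200.0) + 0.2
    alpha[:, 1] = 1.0
    alpha[:, 2] = 1.0 + flat_elev / 1000.0
    alpha[:, 3] = np.where(urban.ravel(), 3.0, 0.8)
    # vectorised Dirichlet with per-cell alpha via Gamma draws
    g = rng.gamma(alpha)
    cover = g / g.sum(axis=1, keepdims=True)

    muni = _municipality_labels(nr, nc, config.n_municipalities)

    df = pd.DataFrame({
        "cell_id": [f"c{r:03d}_{c:03d}" for r, c in zip(rows.ravel(), cols.ravel())],
        "row": rows.ravel(),
        "col": cols.ravel(),
        "elevation": elevation.ravel(),
        "bio01": bio01.ravel(),
        "bio04": bio04.ravel(),
        "pel_abu": pel_abu.ravel(),
        "pel_neigh": 0.0,
        "wood": cover[:, 0],
        "eco": cover[:, 1],
        "grass": cover[:, 2],
        "municipality": muni.ravel(),
        "urban": urban.ravel(),
    })
    grid = LandscapeGrid(cells=df, n_rows=nr, n_cols=nc)
    grid.refresh_pel_neigh()
    grid.validate()
    return grid


def _grow_villages(rng: np.random.Generator, elevation: np.ndarray,
                   config: LandscapeConfig) -> np.ndarray:
    """Grow contiguous urban patches, seeded preferentially at low elevation."""
    nr, nc = elevation.shape
    target = int(round(config.urban_fraction * nr * nc))
    urban = np.zeros((nr, nc), dtype=bool)
    if target == 0:
        return urban
    n_villages = max(1, int(round(target / config.village_size)))
    eligible = elevation <= config.urban_max_elev
    # seed weight decays with elevation above the valley floor
    w = np.where(eligible, np.exp(-(elevation - elevation.min())
                                  / config.village_elev_decay), 0.0)
    if w.sum() == 0:
        return urban
    flat_idx = rng.choice(nr * nc, size=min(n_villages, int(eligible.sum())),
                          replace=False, p=(w / w.sum()).ravel())
    frontier = [divmod(int(i), nc) for i in flat_idx]
    for r, c in frontier:
        urban[r, c] = True
    # breadth-first growth around seeds until the target count is reached
    while urban.sum() < target and frontier:
        r, c = frontier.pop(rng.integers(len(frontier)))
        neigh = [(r + dr, c + dc) for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))]
        rng.shuffle(neigh)
        for rr, cc in neigh:
            if (0 <= rr < nr and 0 <= cc < nc and not urban[rr, cc]
                    and eligible[rr, cc]):
                urban[rr, cc] = True
                frontier.append((rr, cc))
                if urban.sum() >= target:
                    break
        else:
            continue
    return urban


def _municipality_labels(nr: int, nc: int, n_muni: int) -> np.ndarray:
    """Partition the grid into contiguous blocks labelled M01, M02, ..."""
    n_row_bands = max(1, int(np.ceil(n_muni / 2)))
    n_col_bands = 2 if n_muni > 1 else 1
    row_band = np.minimum((np.arange(nr) * n_row_bands) // max(nr, 1), n_row_bands - 1)
    col_band = np.minimum((np.arange(nc) * n_col_bands) // max(nc, 1), n_col_bands - 1)
    rb, cb = np.meshgrid(row_band, col_band, indexing="ij")
    idx = rb * n_col_bands + cb
    return np.array([f"M{int(i) + 1:02d}" for i in idx.ravel()]).reshape(nr, nc)
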