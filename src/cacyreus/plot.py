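"""Diagnostic and map plotting helpers.

Thin matplotlib wrappers over the tabular outputs: residual diagnostics
for a fitted abundance model, response curves for the suitability model,
per-cell maps and elevation profiles for scenario comparisons.  Each
function draws on a provided (or fresh) Axes and returns it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib
import matplotlib.pyplot as plt

from .gof import residual_table
from .landscape import LandscapeGrid
from .maxent import MaxentFit
from .nmixture import NMixtureResults


def _axes(ax):
    if ax is None:
        _, ax = plt.subplots()
    return ax


def plot_residuals(res: NMixtureResults, ax=None):
    """Pearson residuals against fitted per-visit counts."""
    tab = residual_table(res)
    ax = _axes(ax)
    ax.scatter(tab["fitted"], tab["pearson_residual"], s=12, alpha=0.6)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("fitted count  E[N] p")
    ax.set_ylabel("Pearson residual")
    ax.set_title(res.spec.label)
    return ax


def plot_response_curve(fit: MaxentFit, covariate: str, n_points: int = 100,
                        ax=None):
    """Suitability (cloglog ROR) along one covariate, others at their mean."""
    curve = fit.response_curve(covariate, n_points)
    ax = _axes(ax)
    ax.plot(curve[covariate], curve["ror"], color="black")
    ax.set_xlabel(covariate)
    ax.set_ylabel("ROR (cloglog)")
    ax.set_ylim(-0.02, 1.02)
    return ax


def plot_cell_map(grid: LandscapeGrid, values: pd.Series | pd.DataFrame,
                  value_col: str = "E_N", ax=None, cmap: str = "viridis",
                  label: str | None = None):
    """Per-cell values as a raster image in grid coordinates.

    ``values`` is either a Series indexed by cell_id or a map table with
    ``cell_id`` and ``value_col`` columns (cells absent from it are blank).
    """
    if isinstance(values, pd.DataFrame):
        values = values.set_index("cell_id")[value_col]
    arr = np.full((grid.n_rows, grid.n_cols), np.nan)
    lut = grid.cells.set_index("cell_id")
    rows = lut.loc[values.index, "row"].to_numpy()
    cols = lut.loc[values.index, "col"].to_numpy()
    arr[rows, cols] = values.to_numpy(float)
    ax = _axes(ax)
    im = ax.imshow(arr, origin="lower", cmap=cmap)
    ax.figure.colorbar(im, ax=ax, label=label or value_col)
    ax.set_xlabel("grid column")
    ax.set_ylabel("grid row")
    return ax


def plot_elevation_profile(profile: pd.DataFrame, ax=None):
    """Binned mean abundance against elevation, one line per scenario."""
    ax = _axes(ax)
    for label, sub in profile.groupby("scenario", sort=False):
        ax.plot(sub["bin_mid"], sub["mean_E"], marker="o", label=label)
    ax.set_xlabel("elevation (m)")
    ax.set_ylabel("mean expected egg abundance")
    ax.legend()
    return ax
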