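"""Climate-warming and host-plant-management scenario projection.

The best abundance model is projected over the full landscape, covariates
are shifted on their raw (unscaled) scales — an additive temperature
increase, a multiplicative reduction of host-plant pots — re-standardized
with the training scaling record, and the per-cell change in expected egg
abundance is categorized and summarized by municipality and elevation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import LandscapeGrid
from .nmixture import NMixtureResults

CATEGORIES = ("increase", "decrease", "no_change", "new_infestation")


@dataclass(frozen=True)
class ScenarioSpec:
    """A covariate shift applied on the raw scale before re-scaling.

    ``delta_bio01`` adds degrees Celsius to the annual mean temperature
    (default +1.5, the mid-century warming projection for the Alps under
    a low-emission pathway); ``pel_multiplier`` scales host-plant pot
    counts (default 0.5, a 50% reduction campaign).
    """

    delta_bio01: float = 1.5
    pel_multiplier: float = 0.5
    label: str = "scenario"

    def __post_init__(self) -> None:
        if self.pel_multiplier < 0:
            raise ValueError("pel_multiplier must be >= 0")


def round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to the nearest integer, halves away from zero-point-five up.

    Egg numbers are integers; classifying changes on rounded values keeps
    tiny float drifts from creating spurious categories.
    """
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def project_map(res: NMixtureResults, grid: LandscapeGrid,
                scenario: ScenarioSpec | None = None,
                cells: str = "pots", recompute_neigh: bool = True,
                scale_neigh: bool = True) -> pd.DataFrame:
    """Expected egg abundance per cell, optionally under a scenario.

    The scenario acts on unscaled covariates: ``bio01 += delta``;
    ``pel_abu *= multiplier`` with ``pel_neigh`` recomputed from the
    scaled pot field when the grid topology is available (else multiplied
    directly; ``scale_neigh=False`` leaves it untouched).  Projection is
    restricted to host-plant cells (``cells="pots"``, the host-obligate
    default) or covers everything (``cells="all"``).

    Returns ``cell_id, E_N, host_free`` (plus ``se_E_N`` when available).
    """
    if not res.scaling_record:
        raise ValueError("results carry no scaling record; fit on "
                         "standardized data first")
    table = grid.cells.copy()
    host_free = None
    if scenario is not None:
        table["bio01"] = table["bio01"] + scenario.delta_bio01
        table["pel_abu"] = table["pel_abu"] * scenario.pel_multiplier
        if scale_neigh:
            if recompute_neigh:
                shifted = LandscapeGrid(cells=table, n_rows=grid.n_rows,
                                        n_cols=grid.n_cols,
                                        resolution_m=grid.resolution_m)
                table["pel_neigh"] = shifted.neighbour_sum("pel_abu")
            else:
                table["pel_neigh"] = table["pel_neigh"] * scenario.pel_multiplier
        host_free = table["pel_abu"] <= 0
    if cells == "pots":
        keep = grid.cells["pel_abu"] > 0
    elif cells == "all":
        keep = pd.Series(True, index=table.index)
    else:
        raise ValueError("cells must be 'pots' or 'all'")
    table = table[keep]
    pred = res.predict(table)
    out = pd.DataFrame({
        "cell_id": table["cell_id"].to_numpy(),
        "E_N": pred["E_N"].to_numpy(),
        "host_free": (host_free[keep].to_numpy() if host_free is not None
                      else (table["pel_abu"] <= 0).to_numpy()),
    })
    if "se_E_N" in pred:
        out["se_E_N"] = pred["se_E_N"].to_numpy()
    return out


@dataclass
class ScenarioResult:
    """Per-cell baseline vs scenario comparison with change categories."""

    per_cell: pd.DataFrame   # cell_id, baseline_E, scenario_E, rounded_*, category
    label: str = "scenario"

    def counts(self) -> dict[str, int]:
        cat = self.per_cell["category"]
        n_new = int((self.per_cell["new_infestation"]).sum())
        return {
            "increase": int((cat == "increase").sum()),
            "decrease": int((cat == "decrease").sum()),
            "no_change": int((cat == "no_change").sum()),
            "new_infestation": n_new,
            "changed": int((cat != "no_change").sum()),
            "total": len(self.per_cell),
        }

    def summary(self) -> pd.DataFrame:
        """Percentages of cells per change category (counts alongside).

        Increases, decreases and no-change partition the cells; new
        infestations are the sub-category of increases whose rounded
        baseline was zero.
        """
        c = self.counts()
        n = max(c["total"], 1)
        rows = [
            ("cells with egg abundance changes", c["changed"]),
            ("cells with egg increases", c["increase"]),
            ("cells with egg decreases", c["decrease"]),
            ("cells with new egg infestations", c["new_infestation"]),
            ("cells with no changes", c["no_change"]),
        ]
        return pd.DataFrame({
            "category": [r[0] for r in rows],
            "percent": [100.0 * r[1] / n for r in rows],
            "count": [r[1] for r in rows],
        })


def categorize_changes(baseline: pd.DataFrame, scenario: pd.DataFrame,
                       label: str = "scenario") -> ScenarioResult:
    """Classify per-cell changes between two projected maps.

    Both maps must cover the same cells (``cell_id, E_N``).  Values are
    rounded half-up to whole eggs first; a cell whose rounded count moves
    0 -> >=1 is a new infestation (and counts as an increase).
    """
    b = baseline.set_index("cell_id")["E_N"]
    s = scenario.set_index("cell_id")["E_N"]
    if set(b.index) != set(s.index):
        raise ValueError("baseline and scenario cover different cell sets")
    s = s.loc[b.index]
    rb = round_half_up(b.to_numpy())
    rs = round_half_up(s.to_numpy())
    category = np.where(rs > rb, "increase",
                        np.where(rs < rb, "decrease", "no_change"))
    new_inf = (rb == 0) & (rs >= 1)
    per_cell = pd.DataFrame({
        "cell_id": b.index.to_numpy(),
        "baseline_E": b.to_numpy(),
        "scenario_E": s.to_numpy(),
        "rounded_baseline": rb.astype(int),
        "rounded_scenario": rs.astype(int),
        "category": category,
        "new_infestation": new_inf,
    })
    return ScenarioResult(per_cell=per_cell, label=label)


def summarize_by_group(result: ScenarioResult, grid: LandscapeGrid,
                       group: str = "municipality") -> pd.DataFrame:
    """Per-group change summary sorted by mean elevation (ascending).

    Columns: group, mean elevation, percent (and count) of cells with
    decreases and increases; groups partition the compared cells.
    """
    if group not in grid.cells.columns:
        raise KeyError(f"grid lacks column {group!r}")
    lut = grid.cells.set_index("cell_id")
    merged = result.per_cell.merge(
        lut[[group, "elevation"]], left_on="cell_id", right_index=True,
        how="left")
    rows = []
    all_groups = list(dict.fromkeys(grid.cells[group]))
    grouped = dict(list(merged.groupby(group, sort=False)))
    grid_elev = grid.cells.groupby(group)["elevation"].mean()
    for g in all_groups:
        sub = grouped.get(g, merged.iloc[0:0])
        n = len(sub)
        n_dec = int((sub["category"] == "decrease").sum())
        n_inc = int((sub["category"] == "increase").sum())
        rows.append({
            group: g,
            "mean_elevation": float(grid_elev[g]),
            "n_cells": n,
            "pct_decrease": 100.0 * n_dec / n if n else 0.0,
            "n_decrease": n_dec,
            "pct_increase": 100.0 * n_inc / n if n else 0.0,
            "n_increase": n_inc,
        })
    return (pd.DataFrame(rows)
            .sort_values("mean_elevation", kind="stable")
            .reset_index(drop=True))


def elevation_profile(maps: list[tuple[str, pd.DataFrame]],
                      grid: LandscapeGrid, n_bins: int = 10) -> pd.DataFrame:
    """Mean expected abundance per equal-width elevation bin per scenario.

    A binned-mean stand-in for a smoothed abundance-vs-elevation trend;
    extreme values are retained (no trimming).
    """
    if n_bins < 2:
        raise ValueError("need at least 2 elevation bins")
    if not maps:
        raise ValueError("need at least one map")
    lut = grid.cells.set_index("cell_id")["elevation"]
    all_cells = pd.Index(sorted(set().union(
        *[set(m["cell_id"]) for _, m in maps])))
    elev = lut.loc[all_cells]
    edges = np.linspace(elev.min(), elev.max(), n_bins + 1)
    rows = []
    for label, m in maps:
        e = lut.loc[m["cell_id"]].to_numpy()
        which = np.clip(np.digitize(e, edges) - 1, 0, n_bins - 1)
        for b in range(n_bins):
            sel = which == b
            rows.append({
                "scenario": label,
                "bin_low": edges[b], "bin_high": edges[b + 1],
                "bin_mid": 0.5 * (edges[b] + edges[b + 1]),
                "n_cells": int(sel.sum()),
                "mean_E": float(m["E_N"].to_numpy()[sel].mean())
                if sel.any() else np.nan,
            })
    return pd.DataFrame(rows)
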