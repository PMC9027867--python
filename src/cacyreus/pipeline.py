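"""End-to-end orchestration: simulate, fit, diagnose, project, report.

Every stage reads only its sub-config and a child random stream spawned
from the single run seed; all artifacts are CSV (plus a JSON manifest of
versions, seeds and settings), so a run is reproducible byte for byte.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .countdata import collinearity_filter
from .gof import gof_bootstrap, residual_table
from .io import write_counts, write_grid, write_points
from .landscape import make_landscape
from .maxent import MaxentModel, evaluate_tss, sample_background
from .nmixture import NMixtureResults
from .scenario import (ScenarioSpec, categorize_changes, elevation_profile,
                       project_map, summarize_by_group)
from .selection import two_step_selection
from .survey import TruthParams, default_truth, simulate_counts, \
    simulate_opportunistic, stratified_design

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial artifacts are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _truth_from_config(cfg: RunConfig) -> TruthParams:
    t = default_truth(mixture=cfg.truth.mixture, psi=cfg.truth.psi)
    if cfg.truth.beta:
        t.beta = dict(cfg.truth.beta)
    if cfg.truth.alpha:
        t.alpha = dict(cfg.truth.alpha)
    return t


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> Path:
    """Run the full analysis; returns the run directory.

    Artifacts: grid/counts/points CSVs, the three selection tables, the
    coefficient table, GOF report, maxent contribution/ROR/response/TSS
    tables, scenario summaries, elevation profile and ``manifest.json``.
    """
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    manifest: dict = {
        "package": "cacyreus", "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__, "pandas": pd.__version__,
        "seed": config.seed, "config": config.to_dict(), "stages": {},
    }

    stage = "simulate"
    try:
        rng = np.random.default_rng(seeds[0])
        grid = make_landscape(config.landscape, rng)
        design = stratified_design(grid, config.design.bands,
                                   config.design.n_per_band,
                                   config.design.visits,
                                   rng, eligibility=config.design.eligibility)
        truth = _truth_from_config(config)
        data = simulate_counts(grid, design, truth, rng)
        points = simulate_opportunistic(grid, truth, config.maxent.n_points,
                                        config.maxent.bias_strength, rng)
        write_grid(grid, out / "grid.csv")
        write_counts(data, out / "counts.csv")
        write_points(points, out / "points.csv")
        design.selected_cells.to_csv(out / "design.csv", index=False)
        manifest["stages"][stage] = {
            "n_cells": len(grid), "n_sites": design.n_sites,
            "n_site_visits": design.n_site_visits, "n_points": len(points),
        }
        logger.info("simulate: %d cells, %d sites, %d site-visits",
                    len(grid), design.n_sites, design.n_site_visits)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "fit-nmix"
    try:
        retained, dropped = collinearity_filter(
            data, config.model.covariate_candidates,
            config.model.collinearity_threshold)
        pd.DataFrame(dropped, columns=["dropped", "against", "r"]).to_csv(
            out / "collinearity_dropped.csv", index=False)
        scaled = data.standardize(retained + ["pel_ava"])
        abundance_candidates = _abundance_ladder(retained)
        sel = two_step_selection(
            scaled, abundance_candidates=abundance_candidates,
            mixtures=tuple(config.model.mixtures),
            k_trunc_cap=config.model.k_trunc_cap)
        sel.detection_table.to_csv(out / "selection_detection.csv", index=False)
        sel.abundance_table.to_csv(out / "selection_abundance.csv", index=False)
        sel.mixture_table.to_csv(out / "selection_mixture.csv", index=False)
        best = sel.best_fit
        _write_coefficients(best, out / "coefficients.csv")
        (out / "model_summary.txt").write_text(best.summary() + "\n")
        manifest["stages"][stage] = {
            "retained_covariates": retained,
            "best_model": best.spec.label, "aicc": best.aicc,
            "converged": best.converged,
        }
        logger.info("fit-nmix: best %s (AICc %.2f)", best.spec.label, best.aicc)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "gof"
    gof = None
    if config.gof.enabled:
        try:
            gof = gof_bootstrap(best, config.gof.replicates,
                                seed=int(seeds[1].generate_state(1)[0] % 2**31))
            (out / "gof.txt").write_text(gof.summary() + "\n")
            pd.DataFrame({"chisq_boot": gof.chisq_boot}).to_csv(
                out / "gof_bootstrap.csv", index=False)
            residual_table(best).to_csv(out / "residuals.csv", index=False)
            if gof.c_hat > 1.0:
                best = best.inflate_vcov(gof.c_hat)
                _write_coefficients(best, out / "coefficients_inflated.csv")
            manifest["stages"][stage] = {
                "p_value": gof.p_value, "c_hat": gof.c_hat,
                "replicates": gof.replicates, "reliable": gof.reliable,
            }
            logger.info("gof: p=%.3f c-hat=%.2f", gof.p_value, gof.c_hat)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    stage = "fit-maxent"
    try:
        mx_seed = int(seeds[2].generate_state(1)[0] % 2**31)
        presences = points["cell_id"].tolist()
        occ = sample_background(grid, presences, config.maxent.buffer_km,
                                config.maxent.n_background, mx_seed)
        fit = MaxentModel(grid, occ, covariates=config.maxent.covariates,
                          reg_multiplier=config.maxent.reg_multiplier).fit()
        fit.contribution_table(seed=mx_seed).to_csv(out / "maxent_contributions.csv")
        ror = fit.predict(grid, output="cloglog")
        ror.rename("ror_percent").mul(100.0).to_frame().assign(
            cell_id=ror.index).to_csv(out / "ror_map.csv", index=False)
        for cov in config.maxent.covariates:
            fit.response_curve(cov).to_csv(
                out / f"response_{cov}.csv", index=False)
        ev = evaluate_tss(grid, presences, config.maxent.covariates,
                          splits=config.maxent.replicas,
                          train_fraction=config.maxent.train_fraction,
                          seed=mx_seed, buffer_km=config.maxent.buffer_km,
                          n_background=config.maxent.n_background,
                          reg_multiplier=config.maxent.reg_multiplier)
        pd.DataFrame({"tss": ev.tss_replicas}).to_csv(
            out / "tss_replicas.csv", index=False)
        (out / "tss_summary.txt").write_text(
            f"TSS full model (within-sample): {ev.tss_full:.3f}\n"
            f"TSS test replicas ({len(ev.tss_replicas)}): "
            f"mean {ev.mean:.3f} sd {ev.sd:.3f}\n")
        manifest["stages"][stage] = {
            "tss_full": ev.tss_full, "tss_mean": ev.mean, "tss_sd": ev.sd,
            "training_gain": fit.training_gain,
        }
        logger.info("fit-maxent: TSS full %.3f, replicas mean %.3f",
                    ev.tss_full, ev.mean)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "project"
    try:
        baseline = project_map(best, grid, None)
        warming = project_map(best, grid,
                              ScenarioSpec(config.scenario.delta_bio01, 1.0,
                                           "warming"))
        mitigated = project_map(best, grid,
                                ScenarioSpec(config.scenario.delta_bio01,
                                             config.scenario.pel_multiplier,
                                             "warming+reduction"))
        baseline.to_csv(out / "map_baseline.csv", index=False)
        warming.to_csv(out / "map_warming.csv", index=False)
        mitigated.to_csv(out / "map_mitigated.csv", index=False)
        chg_warm = categorize_changes(baseline, warming, "baseline vs warming")
        chg_mit = categorize_changes(warming, mitigated,
                                     "warming vs host-plant reduction")
        summary = pd.concat([
            chg_warm.summary().assign(comparison=chg_warm.label),
            chg_mit.summary().assign(comparison=chg_mit.label),
        ])
        summary.to_csv(out / "scenario_summary.csv", index=False)
        summarize_by_group(chg_mit, grid).to_csv(
            out / "scenario_by_municipality.csv", index=False)
        profile = elevation_profile(
            [("baseline", baseline), ("warming", warming),
             ("warming+reduction", mitigated)],
            grid, config.scenario.n_elevation_bins)
        profile.to_csv(out / "elevation_profile.csv", index=False)
        manifest["stages"][stage] = {
            "n_projected_cells": len(baseline),
            "warming_pct_increase": float(
                100.0 * chg_warm.counts()["increase"]
                / max(chg_warm.counts()["total"], 1)),
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    config.to_yaml(out / "config.yaml")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %s", out)
    return out


def _abundance_ladder(retained: list[str]) -> list[tuple[str, ...]]:
    """Biologically ordered abundance candidates over retained covariates."""
    ladder: list[tuple[str, ...]] = [()]
    for single in ("bio01", "bio04", "pel_abu", "pel_neigh", "wood", "eco",
                   "grass"):
        if single in retained:
            ladder.append((single,))
    if {"bio01", "pel_abu"} <= set(retained):
        ladder.append(("bio01", "pel_abu"))
        if "pel_neigh" in retained:
            ladder.append(("bio01", "pel_abu", "pel_neigh"))
            ladder.append(("bio01", "pel_abu", "pel_abu:bio01", "pel_neigh"))
        else:
            ladder.append(("bio01", "pel_abu", "pel_abu:bio01"))
    return ladder


def _write_coefficients(res: NMixtureResults, path: Path) -> None:
    se = res.bse
    pd.DataFrame({
        "parameter": res.params.index,
        "estimate": res.params.to_numpy(),
        "se": se.to_numpy(),
    }).to_csv(path, index=False)
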