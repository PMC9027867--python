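"""AICc model selection and the two-step covariate-selection workflow.

Candidate models are ranked by the small-sample-corrected Akaike
information criterion; the workflow mirrors the standard hierarchical
practice for N-mixture models: choose the detection structure first while
abundance is held at the null (intercept-only, Poisson) model, then rank
abundance structures under the winning detection structure, and finally
compare count mixtures (P, NB, ZIP) for the winning structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .countdata import CountData
from .nmixture import ModelSpec, NMixtureModel, NMixtureResults

logger = logging.getLogger(__name__)


def selection_table(fits: list[NMixtureResults],
                    labels: list[str] | None = None) -> pd.DataFrame:
    """Rank fitted models by AICc with Akaike weights.

    Columns: ``model, K, AICc, dAICc, weight, cum_weight``; rows sorted
    ascending by AICc so the first row has ``dAICc = 0``; weights sum
    to one.
    """
    if not fits:
        raise ValueError("no fits to rank")
    labels = labels if labels is not None else [f.spec.label for f in fits]
    rows = pd.DataFrame({
        "model": labels,
        "K": [f.k_params for f in fits],
        "AICc": [f.aicc for f in fits],
    }).sort_values("AICc", kind="stable").reset_index(drop=True)
    rows["dAICc"] = rows["AICc"] - rows["AICc"].iloc[0]
    rel = np.exp(-0.5 * rows["dAICc"].to_numpy())
    rows["weight"] = rel / rel.sum()
    rows["cum_weight"] = rows["weight"].cumsum()
    return rows


def _pick_best(fits: list[NMixtureResults], table: pd.DataFrame,
               labels: list[str]) -> tuple[NMixtureResults, bool]:
    """Best model per the dAICc > 2 rule; ties resolved by parsimony."""
    best_label = table["model"].iloc[0]
    contenders = table[table["dAICc"] <= 2.0]
    tie = len(contenders) > 1
    if tie:
        # parsimony: fewest parameters among models within 2 AICc units
        best_label = contenders.sort_values(
            ["K", "AICc"], kind="stable")["model"].iloc[0]
        logger.info("AICc tie (dAICc <= 2) among %s; selecting %r by parsimony",
                    list(contenders["model"]), best_label)
    return fits[labels.index(best_label)], tie


@dataclass
class TwoStepSelection:
    """Outcome of the two-step workflow: one ranking table per step."""

    detection_table: pd.DataFrame
    abundance_table: pd.DataFrame
    mixture_table: pd.DataFrame
    best_fit: NMixtureResults
    best_detection: tuple[str, ...]
    best_abundance: tuple[str, ...]
    best_mixture: str
    ties: dict[str, bool] = field(default_factory=dict)


def _fit_candidates(data: CountData, specs: list[ModelSpec],
                    labels: list[str], **fit_kw):
    fits, kept = [], []
    for spec, label in zip(specs, labels):
        try:
            res = NMixtureModel.from_spec(data, spec).fit(**fit_kw)
        except Exception as exc:  # singular design etc.
            logger.warning("candidate %r failed: %s", label, exc)
            continue
        if not res.converged:
            logger.warning("candidate %r did not converge; excluded", label)
            continue
        fits.append(res)
        kept.append(label)
    if not fits:
        raise RuntimeError("no candidate model converged")
    return fits, kept


def two_step_selection(data: CountData,
                       detection_candidates: list[tuple[str, ...]] | None = None,
                       abundance_candidates: list[tuple[str, ...]] | None = None,
                       mixtures: tuple[str, ...] = ("P", "NB", "ZIP"),
                       **fit_kw) -> TwoStepSelection:
    """Detection structure first, abundance second, mixture third.

    ``detection_candidates`` defaults to the null and the
    host-plant-availability structure; ``abundance_candidates`` to the
    biologically motivated ladder ending in the temperature x host-plant
    interaction model.  Non-converged candidates are excluded from the
    rankings (logged).
    """
    if detection_candidates is None:
        detection_candidates = [(), ("pel_ava",)]
    if abundance_candidates is None:
        abundance_candidates = [
            (),
            ("bio01",),
            ("pel_abu",),
            ("pel_neigh",),
            ("bio01", "pel_abu"),
            ("bio01", "pel_abu", "pel_neigh"),
            ("bio01", "pel_abu", "pel_abu:bio01", "pel_neigh"),
        ]
    if not detection_candidates or not abundance_candidates or not mixtures:
        raise ValueError("candidate lists must be non-empty")

    def det_label(terms):
        return f"p({' + '.join(terms) or '.'}) lam(.)"

    # step 1: detection at null abundance, Poisson mixture
    det_specs = [ModelSpec((), tuple(t), "P") for t in detection_candidates]
    det_labels = [det_label(t) for t in detection_candidates]
    det_fits, det_labels = _fit_candidates(data, det_specs, det_labels, **fit_kw)
    det_table = selection_table(det_fits, det_labels)
    det_best, det_tie = _pick_best(det_fits, det_table, det_labels)
    best_det = det_best.spec.detection_terms

    # step 2: abundance structures under the winning detection structure
    ab_specs = [ModelSpec(tuple(t), best_det, "P") for t in abundance_candidates]
    ab_labels = [s.label for s in ab_specs]
    ab_fits, ab_labels = _fit_candidates(data, ab_specs, ab_labels, **fit_kw)
    ab_table = selection_table(ab_fits, ab_labels)
    ab_best, ab_tie = _pick_best(ab_fits, ab_table, ab_labels)
    best_ab = ab_best.spec.abundance_terms

    # step 3: refit the winner under each mixture
    mix_specs = [ModelSpec(best_ab, best_det, m) for m in mixtures]
    mix_fits, mix_labels = _fit_candidates(data, mix_specs, list(mixtures),
                                           **fit_kw)
    mix_table = selection_table(mix_fits, mix_labels)
    mix_best, mix_tie = _pick_best(mix_fits, mix_table, mix_labels)

    return TwoStepSelection(
        detection_table=det_table, abundance_table=ab_table,
        mixture_table=mix_table, best_fit=mix_best,
        best_detection=best_det, best_abundance=best_ab,
        best_mixture=mix_best.spec.mixture,
        ties={"detection": det_tie, "abundance": ab_tie, "mixture": mix_tie})
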