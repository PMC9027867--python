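"""Presence-only maximum-entropy species distribution modelling.

The model estimates the relative occurrence rate (ROR): a Gibbs density
over landscape cells, exp(eta(x))/Z, constrained by the covariate values
at presence points against a background (pseudo-absence) sample drawn from
the accessible landscape — here, cells within a buffer distance of the
presences, which corrects for spatially biased recording effort.  Features
are linear and quadratic transforms of min-max scaled covariates; weights
maximize the penalized log-likelihood (L1 regularization) by monotone
coordinate-wise ascent.

Model/Results usage::

    occ = sample_background(grid, presence_cells, buffer_km=2.5,
                            n_background=1000, seed=0)
    fit = MaxentModel(grid, occ, covariates=["bio01", "pel_abu"]).fit()
    ror = fit.predict(grid, output="cloglog")
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import rankdata

from .landscape import LandscapeGrid

logger = logging.getLogger(__name__)


@dataclass
class OccurrenceSet:
    """Presence cells plus a buffered background (pseudo-absence) sample."""

    presence_cells: list[str]
    background_cells: list[str]
    buffer_km: float = 2.5

    def __post_init__(self) -> None:
        overlap = set(self.presence_cells) & set(self.background_cells)
        if overlap:
            raise ValueError(f"background overlaps presences: {sorted(overlap)[:5]}")


def sample_background(grid: LandscapeGrid, presences: list[str],
                      buffer_km: float = 2.5, n_background: int = 1000,
                      seed: int | np.random.Generator = 0) -> OccurrenceSet:
    """Uniform background sample within ``buffer_km`` of any presence.

    Distances are Euclidean between cell centres on the grid's metric
    coordinates (2.5 km on a 250 m grid is a 10-cell radius).  Presence
    cells themselves are excluded.  If fewer eligible cells exist than
    requested, all are taken (logged).
    """
    presences = list(presences)
    if not presences:
        raise ValueError("need at least one presence cell")
    rng = np.random.default_rng(seed)
    cells = grid.cells["cell_id"].to_numpy()
    centres = grid.cell_centres()
    pres_set = set(presences)
    pres_idx = np.flatnonzero(np.isin(cells, list(pres_set)))
    if pres_idx.size == 0:
        raise ValueError("presence cells not found in grid")
    d2max = (buffer_km * 1000.0) ** 2
    # min squared distance to any presence centre
    diff = centres[:, None, :] - centres[pres_idx][None, :, :]
    d2 = (diff ** 2).sum(axis=2).min(axis=1)
    eligible = (d2 <= d2max) & ~np.isin(cells, list(pres_set))
    pool = cells[eligible]
    if pool.size == 0:
        raise ValueError("no eligible background cells within the buffer")
    if pool.size <= n_background:
        logger.info("only %d eligible background cells (requested %d); "
                    "taking all", pool.size, n_background)
        chosen = pool
    else:
        chosen = rng.choice(pool, size=n_background, replace=False)
    return OccurrenceSet(presence_cells=presences,
                         background_cells=list(chosen), buffer_km=buffer_km)


def auc_score(pos: np.ndarray, neg: np.ndarray) -> float:
    """Rank-based AUC of positive vs negative scores."""
    scores = np.concatenate([pos, neg])
    ranks = rankdata(scores)
    return float((ranks[:len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0)
                 / (len(pos) * len(neg)))


class MaxentModel:
    """Maximum-entropy presence/background model over a landscape grid."""

    def __init__(self, grid: LandscapeGrid, occ: OccurrenceSet,
                 covariates: list[str] = ("bio01", "bio04", "pel_abu", "pel_neigh"),
                 features: tuple[str, ...] = ("linear", "quadratic"),
                 reg_multiplier: float = 1.0):
        if len(occ.presence_cells) < 5:
            raise ValueError("need at least 5 presences")
        unknown = set(features) - {"linear", "quadratic"}
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
        self.grid = grid
        self.occ = occ
        self.covariates = list(covariates)
        self.features = tuple(features)
        self.reg_multiplier = float(reg_multiplier)

        lut = grid.cells.set_index("cell_id")
        # normalization set: presences (unique) + background
        self.norm_cells = list(dict.fromkeys(occ.presence_cells)) + list(
            occ.background_cells)
        raw = lut.loc[self.norm_cells, self.covariates].to_numpy(float)
        if not np.isfinite(raw).all():
            raise ValueError("non-finite covariates over presence/background")
        self.scaling = {c: (float(raw[:, k].min()), float(raw[:, k].max()))
                        for k, c in enumerate(self.covariates)}
        self.feat, self.feat_names = self._featurize(raw)
        # presence rows within the normalization set (with multiplicity)
        pos = {c: i for i, c in enumerate(self.norm_cells)}
        self.pres_rows = np.array([pos[c] for c in occ.presence_cells])

    def _featurize(self, raw: np.ndarray) -> tuple[np.ndarray, list[str]]:
        cols, names = [], []
        z = np.empty_like(raw)
        for k, c in enumerate(self.covariates):
            lo, hi = self.scaling[c]
            span = hi - lo if hi > lo else 1.0
            z[:, k] = np.clip((raw[:, k] - lo) / span, 0.0, 1.0)
        if "linear" in self.features:
            for k, c in enumerate(self.covariates):
                cols.append(z[:, k])
                names.append(c)
        if "quadratic" in self.features:
            for k, c in enumerate(self.covariates):
                cols.append(z[:, k] ** 2)
                names.append(f"{c}^2")
        return np.column_stack(cols), names

    def _gain(self, eta: np.ndarray) -> float:
        """Log-likelihood per presence relative to the uniform density."""
        return float(eta[self.pres_rows].mean()
                     - (logsumexp(eta) - np.log(len(eta))))

    def fit(self, max_sweeps: int = 500, tol: float = 1e-8) -> "MaxentFit":
        """Coordinate-wise penalized likelihood ascent.

        Each pass updates one feature weight at a time by a damped Newton
        step soft-thresholded against the feature's L1 penalty; steps that
        would not improve the penalized gain are halved (monotone ascent).
        Per-feature positive gain increments, pooled by parent covariate,
        yield the percent-contribution table.
        """
        f = self.feat
        n_feat = f.shape[1]
        pres_mean = f[self.pres_rows].mean(axis=0)
        pen = self.reg_multiplier * (
            f[self.pres_rows].std(axis=0, ddof=0) + 1e-6
        ) / np.sqrt(len(self.pres_rows))
        w = np.zeros(n_feat)
        eta = np.zeros(len(f))
        gain = self._gain(eta)
        contrib = {c: 0.0 for c in self.covariates}

        def penalized(g, wv):
            return g - float(pen @ np.abs(wv))

        converged = False
        for sweep in range(max_sweeps):
            max_step = 0.0
            for j in range(n_feat):
                log_w_all = eta - logsumexp(eta)
                q = np.exp(log_w_all)              # model density over cells
                mu = float(q @ f[:, j])
                var = float(q @ (f[:, j] - mu) ** 2)
                if var < 1e-12:
                    continue
                grad = pres_mean[j] - mu
                target = w[j] + grad / var
                w_new = np.sign(target) * max(abs(target) - pen[j] / var, 0.0)
                step = w_new - w[j]
                if step == 0.0:
                    continue
                # halving line search on the penalized gain
                obj0 = penalized(gain, w)
                for _ in range(25):
                    w_try = w.copy()
                    w_try[j] = w[j] + step
                    eta_try = eta + step * f[:, j]
                    gain_try = self._gain(eta_try)
                    if penalized(gain_try, w_try) >= obj0 - 1e-15:
                        break
                    step *= 0.5
                else:
                    continue
                parent = self.feat_names[j].split("^")[0]
                contrib[parent] += max(gain_try - gain, 0.0)
                w, eta, gain = w_try, eta_try, gain_try
                max_step = max(max_step, abs(step))
            if max_step < tol:
                converged = True
                break
        if not converged and max_step > 1e-3:
            raise RuntimeError(
                f"maxent training did not converge: last sweep moved "
                f"{max_step:.2e} after {max_sweeps} sweeps")

        log_z = float(logsumexp(eta))
        raw = np.exp(eta - log_z)
        entropy = float(-(raw * np.where(raw > 0, np.log(raw), 0.0)).sum())
        total = sum(contrib.values())
        pct = pd.Series({c: (100.0 * v / total if total > 0 else 0.0)
                         for c, v in contrib.items()})
        return MaxentFit(model=self, feature_weights=pd.Series(w, index=self.feat_names),
                         feature_scaling=dict(self.scaling),
                         regularization=self.reg_multiplier,
                         training_gain=gain, log_z=log_z, entropy=entropy,
                         percent_contribution=pct)


@dataclass
class MaxentFit:
    """Trained maxent weights with importance summaries and prediction."""

    model: MaxentModel
    feature_weights: pd.Series
    feature_scaling: dict[str, tuple[float, float]]
    regularization: float
    training_gain: float
    log_z: float
    entropy: float
    percent_contribution: pd.Series
    _perm_importance: pd.Series | None = field(default=None, repr=False)

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        """Eta over arbitrary cells; covariates outside the training range
        are clamped to it (logged)."""
        raw = table[self.model.covariates].to_numpy(float)
        for k, c in enumerate(self.model.covariates):
            lo, hi = self.feature_scaling[c]
            n_out = int(((raw[:, k] < lo) | (raw[:, k] > hi)).sum())
            if n_out:
                logger.info("clamping %d values of %s to training range", n_out, c)
        feat, _ = self.model._featurize(raw)
        return feat @ self.feature_weights.to_numpy()

    def predict(self, grid: LandscapeGrid | pd.DataFrame,
                output: str = "raw") -> pd.Series:
        """Per-cell ROR.

        ``raw`` is the Gibbs density normalized over the training
        presence+background set (sums to 1 there); ``cloglog`` maps it to
        [0, 1] via 1 - exp(-e^H * raw) with H the entropy of the raw
        training distribution.
        """
        table = grid.cells if isinstance(grid, LandscapeGrid) else grid
        eta = self.linear_predictor(table)
        raw = np.exp(eta - self.log_z)
        if output == "raw":
            out = raw
        elif output == "cloglog":
            out = 1.0 - np.exp(-np.exp(self.entropy) * raw)
        else:
            raise ValueError("output must be 'raw' or 'cloglog'")
        index = (table["cell_id"].to_numpy() if "cell_id" in table
                 else np.arange(len(table)))
        return pd.Series(out, index=index, name=f"ror_{output}")

    def response_curve(self, covariate: str, n_points: int = 100) -> pd.DataFrame:
        """Sweep one covariate over its training range, others at their
        presence+background mean; cloglog output."""
        if covariate not in self.model.covariates:
            raise KeyError(f"unknown covariate {covariate!r}")
        lut = self.model.grid.cells.set_index("cell_id")
        base = lut.loc[self.model.norm_cells, self.model.covariates].mean()
        lo, hi = self.feature_scaling[covariate]
        values = np.linspace(lo, hi, n_points)
        table = pd.DataFrame([base] * n_points).reset_index(drop=True)
        table[covariate] = values
        ror = self.predict(table, output="cloglog").to_numpy()
        return pd.DataFrame({covariate: values, "ror": ror})

    def permutation_importance(self, n_repeats: int = 3,
                               seed: int = 0) -> pd.Series:
        """AUC drop when one covariate's values are permuted across the
        presence+background rows, normalized to sum to 100."""
        if self._perm_importance is not None:
            return self._perm_importance
        rng = np.random.default_rng(seed)
        m = self.model
        lut = m.grid.cells.set_index("cell_id")
        table = lut.loc[m.norm_cells, m.covariates].copy()
        eta = self.linear_predictor(table)
        pres, bg = m.pres_rows, np.setdiff1d(np.arange(len(table)), m.pres_rows)
        auc0 = auc_score(eta[pres], eta[bg])
        drops = {}
        for c in m.covariates:
            drop = 0.0
            for _ in range(n_repeats):
                shuffled = table.copy()
                shuffled[c] = rng.permutation(shuffled[c].to_numpy())
                eta_p = self.linear_predictor(shuffled)
                drop += max(auc0 - auc_score(eta_p[pres], eta_p[bg]), 0.0)
            drops[c] = drop / n_repeats
        total = sum(drops.values())
        out = pd.Series({c: (100.0 * v / total if total > 0 else 0.0)
                         for c, v in drops.items()})
        self._perm_importance = out
        return out

    def contribution_table(self, seed: int = 0) -> pd.DataFrame:
        """Percent contribution and permutation importance per covariate,
        dominant variable first."""
        tab = pd.DataFrame({
            "percent_contribution": self.percent_contribution,
            "permutation_importance": self.permutation_importance(seed=seed),
        })
        return tab.sort_values("percent_contribution", ascending=False)

    def summary(self) -> str:
        lines = [
            "MaxEnt presence/background model",
            f"presences : {len(self.model.occ.presence_cells)}   "
            f"background: {len(self.model.occ.background_cells)}",
            f"features  : {', '.join(self.model.features)}   "
            f"regularization x{self.regularization:g}",
            f"training gain: {self.training_gain:.4f}",
            "-" * 56,
            self.contribution_table().to_string(
                float_format=lambda v: f"{v:.1f}"),
        ]
        return "\n".join(lines)


@dataclass
class EvalResult:
    """Train-test evaluation: TSS of the full model and of each replica."""

    tss_full: float
    tss_replicas: np.ndarray
    threshold_rule: str = "max TSS on training split"
    n_skipped: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.tss_replicas))

    @property
    def sd(self) -> float:
        return float(np.std(self.tss_replicas, ddof=1))


def _tss_at(scores_pos: np.ndarray, scores_neg: np.ndarray,
            thr: float) -> float:
    sens = float(np.mean(scores_pos >= thr))
    spec = float(np.mean(scores_neg < thr))
    return sens + spec - 1.0


def _best_threshold(pos: np.ndarray, neg: np.ndarray) -> float:
    cand = np.unique(np.concatenate([pos, neg]))
    best_thr, best = cand[0], -np.inf
    for thr in cand:
        t = _tss_at(pos, neg, thr)
        if t > best:
            best, best_thr = t, thr
    return best_thr


def evaluate_tss(grid: LandscapeGrid, presences: list[str],
                 covariates: list[str], splits: int = 100,
                 train_fraction: float = 0.8,
                 seed: int | np.random.Generator = 0,
                 buffer_km: float = 2.5, n_background: int = 1000,
                 features: tuple[str, ...] = ("linear", "quadratic"),
                 reg_multiplier: float = 1.0) -> EvalResult:
    """True-skill-statistic evaluation under repeated train-test splits.

    Per replica the presences are split ``train_fraction``/rest, a fresh
    background is drawn (within the buffer of all presences) and split the
    same way; the model fit on the training part is thresholded to
    maximize training TSS and scored on the held-out part.  ``tss_full``
    is the within-sample TSS of a fit to all data (labelled as such).
    """
    presences = list(presences)
    rng = np.random.default_rng(seed)
    n_test = max(1, int(round(len(presences) * (1.0 - train_fraction))))
    if len(presences) - n_test < 5:
        raise ValueError("too few presences for the requested split")

    def fit_and_scores(pres_cells, occ):
        model = MaxentModel(grid, occ, covariates=covariates,
                            features=features, reg_multiplier=reg_multiplier)
        fit = model.fit()
        return fit

    # full model, within-sample evaluation
    occ_full = sample_background(grid, presences, buffer_km, n_background, rng)
    fit_full = fit_and_scores(presences, occ_full)
    lut = grid.cells.set_index("cell_id")
    eta_p = fit_full.linear_predictor(lut.loc[presences])
    eta_b = fit_full.linear_predictor(lut.loc[occ_full.background_cells])
    tss_full = _tss_at(eta_p, eta_b, _best_threshold(eta_p, eta_b))

    tss = []
    n_skipped = 0
    for _ in range(splits):
        perm = rng.permutation(len(presences))
        test_p = [presences[i] for i in perm[:n_test]]
        train_p = [presences[i] for i in perm[n_test:]]
        occ = sample_background(grid, presences, buffer_km, n_background, rng)
        bg = list(occ.background_cells)
        rng.shuffle(bg)
        n_bg_test = max(1, int(round(len(bg) * (1.0 - train_fraction))))
        test_b, train_b = bg[:n_bg_test], bg[n_bg_test:]
        try:
            fit = fit_and_scores(train_p, OccurrenceSet(train_p, train_b,
                                                        buffer_km))
            tr_p = fit.linear_predictor(lut.loc[train_p])
            tr_b = fit.linear_predictor(lut.loc[train_b])
            thr = _best_threshold(tr_p, tr_b)
            te_p = fit.linear_predictor(lut.loc[test_p])
            te_b = fit.linear_predictor(lut.loc[test_b])
            tss.append(_tss_at(te_p, te_b, thr))
        except (ValueError, RuntimeError) as exc:
            logger.warning("replica skipped: %s", exc)
            n_skipped += 1
    return EvalResult(tss_full=tss_full, tss_replicas=np.asarray(tss),
                      n_skipped=n_skipped)
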