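"""Goodness-of-fit diagnostics for fitted N-mixture models.

Parametric-bootstrap chi-square test: simulate replicate data sets from
the fitted model, refit the same structure to each, and compare the
observed chi-square statistic with its bootstrap distribution.  The
overdispersion factor c-hat (observed statistic over the bootstrap mean)
feeds variance inflation when the model underfits the data's spread.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .nmixture import NMixtureResults

logger = logging.getLogger(__name__)

#: guard added to fitted values in chi-square/Pearson denominators
EPS = 1e-6


def chisq_statistic(y: np.ndarray, fitted: np.ndarray) -> float:
    """Site-visit level chi-square: sum (y - yhat)^2 / (yhat + eps)."""
    obs = np.isfinite(y) & np.isfinite(fitted)
    resid2 = (y[obs] - fitted[obs]) ** 2
    return float((resid2 / (fitted[obs] + EPS)).sum())


@dataclass
class GofResult:
    """Parametric-bootstrap goodness-of-fit outcome."""

    chisq_obs: float
    chisq_boot: np.ndarray
    replicates: int
    seed: int
    n_failed: int = 0

    @property
    def p_value(self) -> float:
        """Proportion of bootstrap statistics at or above the observed one."""
        return float(np.mean(self.chisq_boot >= self.chisq_obs))

    @property
    def c_hat(self) -> float:
        """Overdispersion factor: observed chi-square / bootstrap mean."""
        return float(self.chisq_obs / self.chisq_boot.mean())

    @property
    def reliable(self) -> bool:
        """False when over 20% of bootstrap refits failed to converge."""
        return self.n_failed <= 0.2 * self.replicates

    def summary(self) -> str:
        lines = [
            "Parametric bootstrap goodness of fit (chi-square)",
            f"observed chi-square : {self.chisq_obs:.2f}",
            f"bootstrap replicates: {self.replicates} "
            f"(non-converged: {self.n_failed})",
            f"bootstrap mean      : {self.chisq_boot.mean():.2f}",
            f"p-value             : {self.p_value:.4f}",
            f"c-hat               : {self.c_hat:.3f}",
        ]
        if self.c_hat > 2.0:
            lines.append("warning: c-hat > 2 indicates weak model robustness")
        if not self.reliable:
            lines.append("warning: result unreliable "
                         "(>20% of bootstrap refits non-converged)")
        return "\n".join(lines)


def _fitted_matrix(res: NMixtureResults, y_like: np.ndarray) -> np.ndarray:
    """Per-visit expected counts E[N] p as an array shaped like y."""
    model = res.model
    if model is None:
        raise ValueError("results must be bound to data")
    lam = np.exp(np.clip(model.x_ab @ res.beta.to_numpy(), -50, 50))
    if model.fixed_p is not None:
        p = np.full(lam.shape, model.fixed_p)
    else:
        p = expit(model.x_det @ res.alpha.to_numpy())
    fitted = (1.0 - res.psi) * lam * p
    out = np.repeat(fitted[:, None], y_like.shape[1], axis=1)
    out[~np.isfinite(y_like)] = np.nan
    return out


def gof_bootstrap(res: NMixtureResults, replicates: int = 1000,
                  seed: int = 0, warm_start: bool = True) -> GofResult:
    """Parametric-bootstrap chi-square test of goodness of fit.

    Each replicate simulates counts from the fitted model over the same
    design, refits the same model structure (warm-started at the parent
    estimates to cut runtime), and recomputes the statistic at the
    replicate's own estimates.
    """
    if res.model is None:
        raise ValueError("results must be bound to data")
    if not res.converged:
        logger.warning("parent fit did not converge; GOF may be unreliable")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    model = res.model
    y_obs = model.y
    chisq_obs = chisq_statistic(y_obs, _fitted_matrix(res, y_obs))

    rng = np.random.default_rng(seed)
    start = res.params.to_numpy() if warm_start else None
    # per-site truncation bound implied by the parent fit, reused across
    # replicates (the refits stay in its neighbourhood)
    from .nmixture import _required_k_site
    lam = np.exp(np.clip(model.x_ab @ res.beta.to_numpy(), -50, 50))
    theta = res.theta if res.spec.mixture == "NB" else None
    ymax = np.nanmax(np.nan_to_num(y_obs), axis=1).astype(int)
    k_site = _required_k_site(lam, res.spec.mixture, theta, ymax) + 20
    boot = np.empty(replicates)
    n_failed = 0
    boot_model = copy.copy(model)
    for r in range(replicates):
        y_sim = res.simulate_array(rng)
        boot_model = copy.copy(model)
        boot_model.y = y_sim
        try:
            boot_res = boot_model.fit(start=start, k_trunc=k_site,
                                      compute_vcov=False)
        except Exception as exc:
            logger.warning("bootstrap refit %d failed: %s", r, exc)
            n_failed += 1
            boot[r] = np.nan
            continue
        if not boot_res.converged:
            # a statistic computed away from the MLE is not a draw from
            # the null distribution
            n_failed += 1
            boot[r] = np.nan
            continue
        boot[r] = chisq_statistic(y_sim, _fitted_matrix(boot_res, y_sim))
    boot = boot[np.isfinite(boot)]
    if boot.size == 0:
        raise RuntimeError("all bootstrap refits failed")
    return GofResult(chisq_obs=chisq_obs, chisq_boot=boot,
                     replicates=replicates, seed=int(seed), n_failed=n_failed)


def inflate_vcov(res: NMixtureResults, c_hat: float) -> NMixtureResults:
    """Scale the variance matrix by ``c_hat`` when ``c_hat > 1``.

    Standard errors grow by sqrt(c_hat); point estimates are untouched;
    no deflation is applied for ``c_hat <= 1``.
    """
    return res.inflate_vcov(c_hat)


def residual_table(res: NMixtureResults) -> pd.DataFrame:
    """Observed, fitted, raw and Pearson residuals per site-visit.

    The Pearson denominator uses the same epsilon guard as the GOF
    statistic; the table drives the residuals-vs-fitted diagnostic plot.
    """
    if res.model is None:
        raise ValueError("results must be bound to data")
    data = res.model.data
    y = data.y.to_numpy(float)
    fitted = _fitted_matrix(res, y)
    rows = []
    for i, site in enumerate(data.y.index):
        for j, visit in enumerate(data.y.columns):
            if not np.isfinite(y[i, j]):
                continue
            raw = y[i, j] - fitted[i, j]
            rows.append({
                "site_id": site, "visit": visit,
                "observed": y[i, j], "fitted": fitted[i, j],
                "raw_residual": raw,
                "pearson_residual": raw / np.sqrt(fitted[i, j] + EPS),
            })
    return pd.DataFrame(rows)
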