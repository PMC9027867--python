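"""Binomial N-mixture models for repeated counts with imperfect detection.

The model: latent abundance ``N_i`` at site ``i`` follows a count mixture
(Poisson ``P``, negative binomial ``NB`` with variance ``lam + lam^2/theta``,
or zero-inflated Poisson ``ZIP`` with extra mass ``psi`` at zero), with
``log lam_i = x_i' beta``; each of ``J`` visits observes
``y_ij ~ Binomial(N_i, p_i)`` with ``logit p_i = w_i' alpha``.  The
likelihood marginalizes ``N_i`` over ``max_j y_ij .. K_trunc``:

    L_i = sum_N g(N; lam_i) prod_j Binom(y_ij; N, p_i)

Everything is computed in log space; the gradient is analytic via the
posterior distribution of ``N_i`` given the data, which makes repeated
fitting (bootstrap, model selection, simulation studies) fast.

Usage follows the Model/Results convention::

    model = NMixtureModel(data, abundance=["bio01", "pel_abu"],
                          detection=["pel_ava"], mixture="ZIP")
    res = model.fit()
    res.summary()
    res.predict(newdata)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import digamma, expit, gammaln

from .countdata import CountData, apply_scaling

__all__ = [
    "ModelSpec", "NMixtureModel", "NMixtureResults", "aicc",
    "nmix_negloglik",
]

_LOGEPS = -700.0  # exp() underflow floor


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion corrected for small samples.

    ``AICc = -2 loglik + 2K + 2K(K+1)/(n - K - 1)``; requires
    ``n - K - 1 > 0``.
    """
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, K={k} (need n > K + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


@dataclass(frozen=True)
class ModelSpec:
    """Model structure: covariate terms for abundance and detection.

    Terms are covariate names; ``"a:b"`` denotes an interaction (the
    product of the two standardized columns).  Intercepts are implicit.
    """

    abundance_terms: tuple[str, ...] = ()
    detection_terms: tuple[str, ...] = ()
    mixture: str = "P"

    def __post_init__(self) -> None:
        if self.mixture not in {"P", "NB", "ZIP"}:
            raise ValueError("mixture must be one of P, NB, ZIP")

    @property
    def label(self) -> str:
        det = " + ".join(self.detection_terms) or "."
        ab = " + ".join(self.abundance_terms) or "."
        return f"p({det}) lam({ab}) [{self.mixture}]"


def _term_column(lookup, term: str) -> np.ndarray:
    col = None
    for part in term.split(":"):
        x = np.asarray(lookup(part), dtype=float)
        col = x if col is None else col * x
    return col


def build_design(data: CountData, terms: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    """Design matrix with an intercept column followed by the terms."""
    cols = [np.ones(data.n_sites)]
    names = ["intercept"]
    for term in terms:
        cols.append(_term_column(lambda n: data.covariate(n).to_numpy(float), term))
        names.append(term)
    return np.column_stack(cols), names


class _NMixCore:
    """Precomputed likelihood machinery for fixed data and truncation bound.

    Heavy integer-combinatorics tables depend only on ``y`` and ``K``, so
    they are built once; each ``value_and_grad`` call is then a handful of
    elementwise array operations over an (M, K+1) grid.
    """

    def __init__(self, y: np.ndarray, x_ab: np.ndarray, x_det: np.ndarray | None,
                 mixture: str, k_trunc: int, fixed_p: float | None = None):
        y = np.asarray(y, dtype=float)
        self.obs = np.isfinite(y)
        if not self.obs.any(axis=1).all():
            raise ValueError("every site needs at least one observed visit")
        ymax = np.nanmax(y, axis=1).astype(int)
        if k_trunc < ymax.max():
            raise ValueError(
                f"K_trunc={k_trunc} below the largest observed count {ymax.max()}")
        self.mixture = mixture
        self.k = int(k_trunc)
        self.x_ab = x_ab
        self.x_det = x_det
        self.fixed_p = fixed_p
        self.n_ab = x_ab.shape[1]
        self.n_det = 0 if x_det is None else x_det.shape[1]
        self.n_extra = 1 if mixture in {"NB", "ZIP"} else 0
        self.n_params = self.n_ab + self.n_det + self.n_extra

        m = y.shape[0]
        self.m = m
        self.s = np.nansum(y, axis=1)               # per-site total count
        self.j_obs = self.obs.sum(axis=1).astype(float)
        self.ymax = ymax

        n_grid = np.arange(self.k + 1)
        self.n_grid = n_grid.astype(float)
        gl = gammaln(np.arange(self.k + 2, dtype=float) + 1.0)  # gl[n] = log n!

        # sum_j log C(N, y_ij) for N >= ymax_i, else -inf
        yi = np.nan_to_num(y)[:, :, None]
        valid = self.obs[:, :, None]
        n3 = n_grid[None, None, :]
        diff = np.clip(n3 - yi, 0, None).astype(int)
        logc = gl[n3] - gl[yi.astype(int)] - gl[diff]
        logc = np.where(valid, logc, 0.0)
        self.log_comb = logc.sum(axis=1)            # (M, K+1)
        self.invalid = n_grid[None, :] < ymax[:, None]
        self.log_fact_n = gl[n_grid]                # log N!

    def unpack(self, params: np.ndarray):
        beta = params[:self.n_ab]
        alpha = params[self.n_ab:self.n_ab + self.n_det]
        extra = params[self.n_ab + self.n_det:] if self.n_extra else None
        return beta, alpha, extra

    def value_and_grad(self, params: np.ndarray) -> tuple[float, np.ndarray]:
        if not np.all(np.isfinite(params)):
            raise ValueError("non-finite parameters")
        beta, alpha, extra = self.unpack(params)
        eta_ab = np.clip(self.x_ab @ beta, -50.0, 50.0)
        lam = np.exp(eta_ab)                         # (M,)
        if self.fixed_p is not None:
            p = np.full(self.m, np.clip(self.fixed_p, 1e-12, 1.0 - 1e-12))
        else:
            p = expit(np.clip(self.x_det @ alpha, -35.0, 35.0))
            p = np.clip(p, 1e-12, 1.0 - 1e-12)
        logp, log1mp = np.log(p), np.log1p(-p)
        n = self.n_grid[None, :]                     # (1, K+1)

        # log g(N; lam) per mixture, (M, K+1)
        if self.mixture == "P":
            log_g = n * eta_ab[:, None] - lam[:, None] - self.log_fact_n[None, :]
        elif self.mixture == "ZIP":
            q = extra[0]
            psi = expit(q)
            log_pois = n * eta_ab[:, None] - lam[:, None] - self.log_fact_n[None, :]
            log_g = np.log1p(-psi) + log_pois
            # N = 0 column: log(psi + (1-psi) e^{-lam})
            log_g[:, 0] = np.logaddexp(np.log(max(psi, 1e-300)),
                                       np.log1p(-psi) - lam)
        else:  # NB, mean lam, size theta
            theta = np.exp(np.clip(extra[0], -30.0, 30.0))
            log_ratio = np.log(theta) - np.log(theta + lam)      # (M,)
            log_g = (gammaln(self.n_grid + theta)[None, :] - gammaln(theta)
                     - self.log_fact_n[None, :]
                     + theta * log_ratio[:, None]
                     + n * (eta_ab[:, None] - np.log(theta + lam)[:, None]))

        a = (log_g + self.log_comb
             + self.s[:, None] * logp[:, None]
             + (self.j_obs[:, None] * n - self.s[:, None]) * log1mp[:, None])
        a = np.where(self.invalid, -np.inf, a)
        amax = a.max(axis=1)
        w = np.exp(a - amax[:, None])      # -inf -> 0, no special handling
        wsum = w.sum(axis=1)
        ll_site = amax + np.log(wsum)
        nll = -float(ll_site.sum())

        w /= wsum[:, None]                 # posterior over latent N

        # d log g / d eta_ab, weighted by the posterior over N
        if self.mixture == "P":
            dg_eta = n - lam[:, None]
        elif self.mixture == "ZIP":
            dg_eta = (n - lam[:, None]).copy()
            denom = psi + (1.0 - psi) * np.exp(-lam)
            dg_eta[:, 0] = -(1.0 - psi) * np.exp(-lam) * lam / denom
        else:
            dg_eta = n - lam[:, None] * (n + theta) / (theta + lam)[:, None]
        d_eta = (w * dg_eta).sum(axis=1)             # (M,)
        grad_beta = -(self.x_ab * d_eta[:, None]).sum(axis=0)

        grads = [grad_beta]
        if self.n_det:
            post_n = (w * n).sum(axis=1)
            d_v = self.s - self.j_obs * post_n * p   # d/d logit p
            grads.append(-(self.x_det * d_v[:, None]).sum(axis=0))
        if self.mixture == "ZIP":
            dg_psi = np.full_like(w, -1.0 / max(1.0 - psi, 1e-300))
            dg_psi[:, 0] = (1.0 - np.exp(-lam)) / denom
            d_q = (w * dg_psi).sum(axis=1).sum() * psi * (1.0 - psi)
            grads.append(np.array([-d_q]))
        elif self.mixture == "NB":
            dig = digamma(self.n_grid + theta)[None, :] - digamma(theta)
            dg_th = theta * (dig + log_ratio[:, None] + 1.0
                             - (n + theta) / (theta + lam)[:, None])
            grads.append(np.array([-(w * dg_th).sum()]))
        return nll, np.concatenate(grads)

    def value(self, params: np.ndarray) -> float:
        return self.value_and_grad(params)[0]


class _GroupedCore:
    """Likelihood over site groups with group-specific truncation bounds.

    Sites whose expected latent abundance is small need a far lower
    truncation bound than the handful of host-plant-rich, warm sites;
    grouping by the per-site bound keeps the (sites x N-grid) arrays
    compact without changing the result.
    """

    def __init__(self, y: np.ndarray, x_ab: np.ndarray, x_det: np.ndarray | None,
                 mixture: str, k_site: np.ndarray, fixed_p: float | None = None,
                 n_groups: int | None = None):
        m = y.shape[0]
        if n_groups is None:
            # splitting pays off only when the N-grid is heterogeneous and
            # the problem is big; tiny problems go in one chunk
            n_groups = int(np.clip(m // 60, 1, 4))
        order = np.argsort(k_site)
        chunks = [c for c in np.array_split(order, min(n_groups, m)) if len(c)]
        self.cores = []
        for idx in chunks:
            k_g = int(k_site[idx].max())
            self.cores.append(_NMixCore(
                y[idx], x_ab[idx], None if x_det is None else x_det[idx],
                mixture, k_g, fixed_p=fixed_p))
        self.k_max = int(k_site.max())
        self.n_params = self.cores[0].n_params

    def unpack(self, params: np.ndarray):
        return self.cores[0].unpack(params)

    def value_and_grad(self, params: np.ndarray) -> tuple[float, np.ndarray]:
        total, grad = 0.0, np.zeros(self.n_params)
        for core in self.cores:
            v, g = core.value_and_grad(params)
            total += v
            grad += g
        return total, grad

    def value(self, params: np.ndarray) -> float:
        return self.value_and_grad(params)[0]


def nmix_negloglik(params: np.ndarray, data: CountData, spec: ModelSpec,
                   k_trunc: int) -> float:
    """Negative marginal log-likelihood at ``params`` (packed beta, alpha,
    then logit-psi or log-theta)."""
    x_ab, _ = build_design(data, tuple(spec.abundance_terms))
    x_det, _ = build_design(data, tuple(spec.detection_terms))
    core = _NMixCore(data.y.to_numpy(float), x_ab, x_det, spec.mixture, k_trunc)
    return core.value(np.asarray(params, dtype=float))


def _fit_core(core: _NMixCore, start: np.ndarray, maxiter: int, gtol: float):
    res = optimize.minimize(core.value_and_grad, start, jac=True,
                            method="L-BFGS-B",
                            options={"maxiter": maxiter, "gtol": gtol,
                                     "ftol": 1e-12})
    return res


def _required_k_site(lam: np.ndarray, mixture: str, theta: float | None,
                     ymax: np.ndarray) -> np.ndarray:
    """Per-site latent-N bound covering all but ~1e-12 of the mixture mass."""
    lam = np.minimum(lam, 1e8)
    if mixture == "NB" and theta is not None:
        hi = stats.nbinom.ppf(1.0 - 1e-12, theta, theta / (theta + lam))
    else:
        hi = stats.poisson.ppf(1.0 - 1e-12, lam)
    return np.maximum(ymax + 10, hi + 10).astype(int)


class NMixtureModel:
    """Binomial N-mixture model bound to a dataset.

    Parameters
    ----------
    data
        A (typically standardized) :class:`~cacyreus.countdata.CountData`.
    abundance, detection
        Covariate terms for the two linear predictors (intercepts are
        implicit; interactions as ``"a:b"``).
    mixture
        ``"P"``, ``"NB"`` or ``"ZIP"``.
    fixed_p
        Optional fixed detection probability (no detection parameters are
        estimated); ``fixed_p=1`` reduces the model to a plain count GLM
        on the visit data.
    """

    def __init__(self, data: CountData, abundance=(), detection=("pel_ava",),
                 mixture: str = "P", fixed_p: float | None = None):
        self.data = data
        self.spec = ModelSpec(tuple(abundance),
                              () if fixed_p is not None else tuple(detection),
                              mixture)
        self.fixed_p = fixed_p
        self.y = data.y.to_numpy(float)
        self.x_ab, ab_names = build_design(data, self.spec.abundance_terms)
        if fixed_p is None:
            self.x_det, det_names = build_design(data, self.spec.detection_terms)
            self.param_names = ([f"lam:{n}" for n in ab_names]
                                + [f"p:{n}" for n in det_names])
        else:
            self.x_det, self.param_names = None, [f"lam:{n}" for n in ab_names]
        if mixture == "ZIP":
            self.param_names.append("psi:logit")
        elif mixture == "NB":
            self.param_names.append("theta:log")
        for mat, what in ((self.x_ab, "abundance"), (self.x_det, "detection")):
            if mat is not None and mat.shape[1] > 1:
                if np.linalg.matrix_rank(mat) < mat.shape[1]:
                    raise ValueError(f"{what} design matrix is rank-deficient")

    @classmethod
    def from_spec(cls, data: CountData, spec: ModelSpec, **kw) -> "NMixtureModel":
        return cls(data, abundance=spec.abundance_terms,
                   detection=spec.detection_terms, mixture=spec.mixture, **kw)

    def start_values(self) -> np.ndarray:
        """Documented starts: ``lam`` intercept at log(mean site max + 0.5),
        all other coefficients 0."""
        site_max = np.nanmax(self.y, axis=1)
        start = np.zeros(len(self.param_names))
        start[0] = np.log(site_max.mean() + 0.5)
        return start

    def _make_core(self, k: int) -> _NMixCore:
        return _NMixCore(self.y, self.x_ab, self.x_det, self.spec.mixture,
                         k, fixed_p=self.fixed_p)

    def fit(self, start: np.ndarray | None = None, k_trunc: int | None = None,
            k_trunc_cap: int = 8000, maxiter: int = 500, gtol: float = 1e-8,
            compute_vcov: bool = True) -> "NMixtureResults":
        """Maximize the marginal likelihood by quasi-Newton (L-BFGS) iteration.

        The truncation bound for the latent-N sum is chosen adaptively:
        after an initial fit, it is enlarged until raising it by 50 changes
        the log-likelihood by under 1e-8 (capped at ``k_trunc_cap``).
        """
        x0 = np.asarray(start, float) if start is not None else self.start_values()
        ymax_site = np.nanmax(self.y, axis=1).astype(int)
        explicit_k = k_trunc is not None
        if explicit_k:
            k_site = np.minimum(np.broadcast_to(
                np.asarray(k_trunc, dtype=int), ymax_site.shape).copy(),
                k_trunc_cap)
            k_site = np.maximum(k_site, ymax_site)
        else:
            k_site = np.minimum(np.maximum(50, 2 * ymax_site + 20), k_trunc_cap)
        k_capped = False

        def grouped(ks):
            return _GroupedCore(self.y, self.x_ab, self.x_det,
                                self.spec.mixture, ks, fixed_p=self.fixed_p)

        core = grouped(k_site)
        res = _fit_core(core, x0, maxiter, gtol)
        for _ in range(12):
            beta, _, extra = core.unpack(res.x)
            lam = np.exp(np.clip(self.x_ab @ beta, -50, 50))
            theta = (np.exp(extra[0]) if self.spec.mixture == "NB" else None)
            needed = _required_k_site(lam, self.spec.mixture, theta, ymax_site)
            k_capped = bool((needed > k_trunc_cap).any())
            k_next = np.minimum(np.maximum(needed, k_site), k_trunc_cap)
            if (k_next > k_site).any():
                k_site = k_next
                core = grouped(k_site)
                res = _fit_core(core, res.x, maxiter, gtol)
                continue
            if explicit_k or (k_site >= k_trunc_cap).all():
                break  # a caller-specified bound is taken as the contract
            # truncation check: +50 must not move the log-likelihood
            probe = grouped(np.minimum(k_site + 50, k_trunc_cap))
            if abs(probe.value(res.x) - res.fun) < 1e-8:
                break
            k_site = np.minimum(k_site + 50, k_trunc_cap)
            core = grouped(k_site)
            res = _fit_core(core, res.x, maxiter, gtol)
        k = int(k_site.max())
        converged = bool(res.success) and not k_capped

        vcov = None
        if compute_vcov:
            vcov = self._observed_vcov(core, res.x)
        return NMixtureResults(
            model=self, spec=self.spec, params=pd.Series(res.x, index=self.param_names),
            llf=-float(res.fun), k_trunc=k, converged=converged,
            vcov=vcov, scaling_record=dict(self.data.scaling_record),
            optimizer_message=str(res.message))

    def _observed_vcov(self, core: _NMixCore, x: np.ndarray) -> pd.DataFrame | None:
        """Observed-information covariance via central differences of the
        analytic gradient."""
        n = len(x)
        hess = np.empty((n, n))
        for i in range(n):
            h = 1e-5 * max(1.0, abs(x[i]))
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            gp = core.value_and_grad(xp)[1]
            gm = core.value_and_grad(xm)[1]
            hess[i] = (gp - gm) / (2.0 * h)
        hess = 0.5 * (hess + hess.T)
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
            return None
        return pd.DataFrame(cov, index=self.param_names, columns=self.param_names)


@dataclass
class NMixtureResults:
    """A fitted N-mixture model: estimates, uncertainty, diagnostics."""

    spec: ModelSpec
    params: pd.Series
    llf: float
    k_trunc: int
    converged: bool
    scaling_record: dict[str, tuple[float, float]]
    vcov: pd.DataFrame | None = None
    model: NMixtureModel | None = None
    optimizer_message: str = ""

    # -- parameter access ------------------------------------------------
    @property
    def beta(self) -> pd.Series:
        sel = self.params.index.str.startswith("lam:")
        out = self.params[sel]
        out.index = [i[4:] for i in out.index]
        return out

    @property
    def alpha(self) -> pd.Series:
        sel = self.params.index.str.startswith("p:")
        out = self.params[sel]
        out.index = [i[2:] for i in out.index]
        return out

    @property
    def psi(self) -> float:
        """Zero-inflation probability (0 unless the mixture is ZIP)."""
        if self.spec.mixture != "ZIP":
            return 0.0
        return float(expit(self.params["psi:logit"]))

    @property
    def theta(self) -> float:
        if self.spec.mixture != "NB":
            return np.inf
        return float(np.exp(self.params["theta:log"]))

    @property
    def k_params(self) -> int:
        return len(self.params)

    @property
    def n_sites(self) -> int:
        return self.model.data.n_sites if self.model is not None else 0

    @property
    def aicc(self) -> float:
        return aicc(self.llf, self.k_params, self.n_sites)

    @property
    def bse(self) -> pd.Series:
        if self.vcov is None:
            return pd.Series(np.nan, index=self.params.index)
        return pd.Series(np.sqrt(np.diag(self.vcov.to_numpy())),
                         index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        se = self.bse
        return pd.DataFrame({"lower": self.params - z * se,
                             "upper": self.params + z * se})

    def inflate_vcov(self, c_hat: float) -> "NMixtureResults":
        """Overdispersion-adjusted copy: vcov scaled by ``c_hat`` when
        ``c_hat > 1`` (standard errors scale by sqrt(c_hat)); estimates
        are untouched and no deflation is applied for ``c_hat <= 1``."""
        if c_hat <= 0:
            raise ValueError("c_hat must be positive")
        if self.vcov is None:
            raise ValueError("no variance matrix available to inflate")
        if c_hat <= 1.0:
            return replace(self)
        return replace(self, vcov=self.vcov * c_hat)

    # -- prediction ------------------------------------------------------
    def _linear_predictors(self, covs: pd.DataFrame, detection: bool = True):
        scaled = apply_scaling(covs, self.scaling_record)

        def lookup(name: str) -> np.ndarray:
            return scaled[name].to_numpy(float)

        def eta(terms: pd.Series) -> np.ndarray:
            out = np.zeros(len(scaled))
            for name, coef in terms.items():
                out += coef * (np.ones(len(scaled)) if name == "intercept"
                               else _term_column(lookup, name))
            return out

        eta_det = eta(self.alpha) if (detection and len(self.alpha)) else None
        return eta(self.beta), eta_det

    def predict(self, newdata: pd.DataFrame | None = None) -> pd.DataFrame:
        """Expected abundance and detection per row of ``newdata``.

        ``newdata`` holds raw (unscaled) covariates; the training scaling
        record is applied before the coefficients.  Returns columns
        ``lam``, ``p``, ``E_N`` (``(1-psi) lam`` under ZIP) and, when a
        variance matrix is available, delta-method ``se_E_N``.
        """
        if newdata is None:
            if self.model is None:
                raise ValueError("no bound data; pass newdata explicitly")
            raw = self.model.data.unstandardize()
            newdata = pd.concat([raw.site_covariates, raw.obs_covariates], axis=1)
        missing = [t for term in self.spec.abundance_terms
                   for t in term.split(":") if t not in newdata.columns]
        if missing:
            raise KeyError(f"newdata lacks covariates: {sorted(set(missing))}")
        det_ok = all(t in newdata.columns for term in self.spec.detection_terms
                     for t in term.split(":"))
        eta_ab, eta_det = self._linear_predictors(newdata, detection=det_ok)
        lam = np.exp(np.clip(eta_ab, -50, 50))
        if eta_det is not None:
            p = expit(eta_det)
        elif det_ok and len(self.alpha) == 0:
            p = np.ones(len(lam))
        else:
            p = np.full(len(lam), np.nan)  # detection covariates absent
        e_n = (1.0 - self.psi) * lam
        out = pd.DataFrame({"eta": eta_ab, "lam": lam, "p": p, "E_N": e_n})
        if self.vcov is not None:
            out["se_E_N"] = self._delta_se(newdata, lam)
        return out

    def _delta_se(self, newdata: pd.DataFrame, lam: np.ndarray) -> np.ndarray:
        scaled = apply_scaling(newdata, self.scaling_record)

        def lookup(name: str) -> np.ndarray:
            return scaled[name].to_numpy(float)

        n = len(scaled)
        grad = np.zeros((n, len(self.params)))
        e_n = (1.0 - self.psi) * lam
        for k, name in enumerate(self.params.index):
            if name.startswith("lam:"):
                t = name[4:]
                col = np.ones(n) if t == "intercept" else _term_column(lookup, t)
                grad[:, k] = e_n * col
            elif name == "psi:logit":
                grad[:, k] = -lam * self.psi * (1.0 - self.psi)
        var = np.einsum("ij,jk,ik->i", grad, self.vcov.to_numpy(), grad)
        return np.sqrt(np.clip(var, 0.0, None))

    def fitted_counts(self) -> pd.DataFrame:
        """Per-visit expected counts ``E[N_i] p_i`` on the bound data
        (NaN where the visit is missing)."""
        if self.model is None:
            raise ValueError("results are not bound to data")
        data = self.model.data
        eta_ab = np.clip(self.model.x_ab @ self.beta.to_numpy(), -50, 50)
        lam = np.exp(eta_ab)
        if self.model.fixed_p is not None:
            p = np.full(data.n_sites, self.model.fixed_p)
        else:
            p = expit(self.model.x_det @ self.alpha.to_numpy())
        fitted = (1.0 - self.psi) * lam * p
        arr = np.repeat(fitted[:, None], data.n_visits, axis=1)
        arr[~np.isfinite(data.y.to_numpy(float))] = np.nan
        return pd.DataFrame(arr, index=data.y.index, columns=data.y.columns)

    def simulate_array(self, seed: int | np.random.Generator = 0) -> np.ndarray:
        """Replicate count matrix from the fitted model as a plain array
        (parametric bootstrap), respecting the missing-visit pattern."""
        if self.model is None:
            raise ValueError("results are not bound to data")
        rng = np.random.default_rng(seed)
        data = self.model.data
        lam = np.exp(np.clip(self.model.x_ab @ self.beta.to_numpy(), -50, 50))
        if self.model.fixed_p is not None:
            p = np.full(data.n_sites, self.model.fixed_p)
        else:
            p = expit(self.model.x_det @ self.alpha.to_numpy())
        mix = self.spec.mixture
        if mix == "P":
            n_latent = rng.poisson(lam)
        elif mix == "NB":
            th = self.theta
            n_latent = rng.negative_binomial(th, th / (th + lam))
        else:
            zero = rng.random(len(lam)) < self.psi
            n_latent = np.where(zero, 0, rng.poisson(lam))
        y = rng.binomial(n_latent[:, None], p[:, None],
                         size=(data.n_sites, data.n_visits)).astype(float)
        y[~np.isfinite(self.model.y)] = np.nan
        return y

    def simulate(self, seed: int | np.random.Generator = 0) -> pd.DataFrame:
        """Like :meth:`simulate_array` but labelled like the original data."""
        data = self.model.data
        return pd.DataFrame(self.simulate_array(seed), index=data.y.index,
                            columns=data.y.columns)

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        se = self.bse
        z = self.params / se
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        tab = pd.DataFrame({"estimate": self.params, "se": se,
                            "z": z, "p>|z|": pvals})
        lines = [
            "N-mixture model results",
            "=" * 64,
            f"structure : {self.spec.label}",
            f"sites     : {self.n_sites}    K truncation: {self.k_trunc}",
            f"logLik    : {self.llf:.3f}    K params: {self.k_params}",
        ]
        if self.n_sites > self.k_params + 1:
            lines.append(f"AICc      : {self.aicc:.2f}")
        if self.spec.mixture == "ZIP":
            lines.append(f"psi (zero inflation): {self.psi:.4f}")
        if self.spec.mixture == "NB":
            lines.append(f"theta (dispersion)  : {self.theta:.4f}")
        lines.append(f"converged : {self.converged}")
        lines.append("-" * 64)
        lines.append(tab.to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)

    @classmethod
    def from_coefficients(cls, abundance: dict[str, float],
                          detection: dict[str, float] | None = None,
                          mixture: str = "ZIP", psi: float = 0.0,
                          theta: float = 1.0,
                          scaling_record: dict | None = None) -> "NMixtureResults":
        """Build a results object from a fixed coefficient vector.

        Used to evaluate or project a published/known parameter set
        without refitting; ``llf`` is NaN and no variance matrix is
        attached.
        """
        detection = detection or {}
        names, values = [], []
        ab_terms, det_terms = [], []
        for k, v in abundance.items():
            names.append(f"lam:{k}")
            values.append(v)
            if k != "intercept":
                ab_terms.append(k)
        for k, v in detection.items():
            names.append(f"p:{k}")
            values.append(v)
            if k != "intercept":
                det_terms.append(k)
        if mixture == "ZIP":
            names.append("psi:logit")
            values.append(float(np.log(psi / (1 - psi))) if 0 < psi < 1
                          else (-35.0 if psi == 0 else 35.0))
        elif mixture == "NB":
            names.append("theta:log")
            values.append(float(np.log(theta)))
        spec = ModelSpec(tuple(ab_terms), tuple(det_terms), mixture)
        return cls(spec=spec, params=pd.Series(values, index=names),
                   llf=np.nan, k_trunc=0, converged=True,
                   scaling_record=dict(scaling_record or {}))
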