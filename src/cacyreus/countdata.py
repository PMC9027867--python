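"""Repeated-count survey data: container, standardization, collinearity screen."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CountData:
    """Site x visit egg counts with site-level covariates.

    Parameters
    ----------
    y
        DataFrame of counts, one row per site, one column per visit
        (``visit_1`` ... ``visit_J``); missing visits are NaN.
    site_covariates
        DataFrame of abundance covariates, indexed like ``y``.
    obs_covariates
        DataFrame of detection covariates (site-level, constant across
        visits), indexed like ``y``; typically the single column
        ``pel_ava`` (host-plant pots accessible during a survey).
    scaling_record
        Per-covariate ``(mean, sd)`` applied by :meth:`standardize`; empty
        when the covariates are on their raw scale.  Scenario projection
        reuses this record so new data are scaled exactly as the training
        data were.
    """

    y: pd.DataFrame
    site_covariates: pd.DataFrame
    obs_covariates: pd.DataFrame
    scaling_record: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        yv = self.y.to_numpy(float)
        obs = np.isfinite(yv)
        if not obs.any(axis=1).all():
            raise ValueError("every site needs at least one non-missing visit")
        vals = yv[obs]
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integers")
        if not (len(self.y) == len(self.site_covariates) == len(self.obs_covariates)):
            raise ValueError("y, site_covariates and obs_covariates disagree in length")

    @property
    def n_sites(self) -> int:
        return len(self.y)

    @property
    def n_visits(self) -> int:
        return self.y.shape[1]

    def covariate(self, name: str) -> pd.Series:
        """Look up a covariate by name in site then observation tables."""
        if name in self.site_covariates.columns:
            return self.site_covariates[name]
        if name in self.obs_covariates.columns:
            return self.obs_covariates[name]
        raise KeyError(f"unknown covariate {name!r}")

    def standardize(self, names: list[str] | None = None) -> "CountData":
        """Return a copy with the named covariates centred and scaled.

        Each column becomes ``(x - mean) / sd``; the ``(mean, sd)`` pairs
        are stored in ``scaling_record``.  Columns already recorded are
        left untouched.
        """
        site = self.site_covariates.copy()
        obs = self.obs_covariates.copy()
        if names is None:
            names = [c for c in site.columns if np.issubdtype(site[c].dtype, np.number)]
            names += [c for c in obs.columns if np.issubdtype(obs[c].dtype, np.number)]
        record = dict(self.scaling_record)
        for name in names:
            if name in record:
                continue
            for table in (site, obs):
                if name not in table.columns:
                    continue
                col = table[name].to_numpy(float)
                mean, sd = float(col.mean()), float(col.std(ddof=1))
                if sd == 0 or not np.isfinite(sd):
                    raise ValueError(f"covariate {name!r} has zero variance")
                table[name] = (col - mean) / sd
                record[name] = (mean, sd)
                break
            else:
                raise KeyError(f"unknown covariate {name!r}")
        return CountData(self.y.copy(), site, obs, record)

    def unstandardize(self) -> "CountData":
        """Invert :meth:`standardize`, restoring the raw covariate scales."""
        site = self.site_covariates.copy()
        obs = self.obs_covariates.copy()
        for name, (mean, sd) in self.scaling_record.items():
            for table in (site, obs):
                if name in table.columns:
                    table[name] = table[name] * sd + mean
        return CountData(self.y.copy(), site, obs, {})

    def to_frame(self) -> pd.DataFrame:
        """Wide table: site_id, visit columns, then covariates."""
        out = self.y.copy()
        for col in self.site_covariates.columns:
            out[col] = self.site_covariates[col]
        for col in self.obs_covariates.columns:
            if col not in out.columns:
                out[col] = self.obs_covariates[col]
        out.insert(0, "site_id", self.y.index)
        return out.reset_index(drop=True)


def apply_scaling(frame: pd.DataFrame,
                  scaling_record: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Standardize columns of ``frame`` using a stored scaling record."""
    out = frame.copy()
    for name, (mean, sd) in scaling_record.items():
        if name in out.columns:
            out[name] = (out[name].to_numpy(float) - mean) / sd
    return out


def collinearity_filter(data: CountData | pd.DataFrame, candidates: list[str],
                        threshold: float = 0.7):
    """Greedy Pearson-correlation screen among candidate covariates.

    While any pair has ``|r| >= threshold`` the member with the larger mean
    absolute correlation against all other remaining candidates is dropped
    (ties break toward the later name in input order).  Mirrors the common
    pre-modelling practice of retaining only predictors with |r| below 0.7.

    Returns
    -------
    retained : list[str]
        Candidate names that survived, in input order.
    dropped : list[tuple[str, str, float]]
        ``(dropped, against, r)`` records, one per removal.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate covariates")
    if isinstance(data, CountData):
        cols = {name: data.covariate(name).to_numpy(float) for name in candidates}
    else:
        cols = {name: data[name].to_numpy(float) for name in candidates}
    for name, v in cols.items():
        if not np.issubdtype(v.dtype, np.number):
            raise ValueError(f"covariate {name!r} is not numeric")
    retained = list(candidates)
    dropped: list[tuple[str, str, float]] = []
    while True:
        X = np.column_stack([cols[n] for n in retained])
        r = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(r, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(r)), r.shape)
        if abs(r[i, j]) < threshold:
            break
        mean_abs = np.abs(r).sum(axis=0) / (len(retained) - 1)
        # drop the member with larger mean |r|; ties -> later in input order
        if mean_abs[i] > mean_abs[j] + 1e-15:
            out = i
        elif mean_abs[j] > mean_abs[i] + 1e-15:
            out = j
        else:
            out = max(i, j)
        keep = j if out == i else i
        dropped.append((retained[out], retained[keep], float(r[i, j])))
        retained.pop(out)
        if len(retained) < 2:
            break
    return retained, dropped
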