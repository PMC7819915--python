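"""ANOVA-based intraclass-correlation repeatability.

Repeatability τ is the fraction of phenotypic variance attributable to
consistent among-individual differences.  The classical one-way ANOVA
estimator: with a groups (individuals) of sizes nᵢ,

    n₀   = (N − Σnᵢ²/N) / (a − 1)
    s²_A = (MS_A − MS_W) / n₀
    τ    = s²_A / (s²_A + MS_W)

with the p-value from the ANOVA F statistic.  Negative among-group
variance estimates are truncated to zero (and flagged).

``adjusted_repeatability`` first removes fixed effects (continuous
covariates and categorical factors) by ordinary least squares and applies
the ANOVA estimator to the residuals, grouped by individual; its standard
error comes from a cluster bootstrap over individuals.  On balanced
designs this estimator agrees closely with a mixed-model (REML)
variance-components estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RepeatabilityResult", "repeatability_anova", "adjusted_repeatability"]


@dataclass
class RepeatabilityResult:
    """Intraclass-correlation repeatability estimate."""

    tau: float
    se: float | None
    p_value: float
    n_groups: int
    n0: float  # effective group size
    variance_among: float
    variance_within: float
    truncated: bool = False  # True when a negative s²_A was clipped to 0

    def to_dict(self) -> dict:
        return {
            "tau": self.tau,
            "se": self.se,
            "p_value": self.p_value,
            "n_groups": self.n_groups,
            "n0": self.n0,
            "variance_among": self.variance_among,
            "variance_within": self.variance_within,
            "truncated": self.truncated,
        }


def repeatability_anova(values, group_ids) -> RepeatabilityResult:
    """One-way ANOVA repeatability of ``values`` grouped by ``group_ids``."""
    y = np.asarray(values, dtype=float)
    g = np.asarray(group_ids)
    if y.shape != g.shape:
        raise ValueError("values and group_ids must have equal length")
    labels, inverse = np.unique(g, return_inverse=True)
    a = labels.size
    n = y.size
    if a < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(inverse)
    if np.any(sizes == 0):
        raise ValueError("every group needs at least one observation")
    if n - a < 1:
        raise ValueError("need replicates beyond one observation per group")
    sums = np.bincount(inverse, weights=y)
    means = sums / sizes
    grand = y.mean()
    ss_a = float(np.sum(sizes * (means - grand) ** 2))
    ss_w = float(np.sum((y - means[inverse]) ** 2))
    ms_a = ss_a / (a - 1)
    ms_w = ss_w / (n - a)
    n0 = (n - np.sum(sizes**2) / n) / (a - 1)
    s2_a = (ms_a - ms_w) / n0
    truncated = False
    if s2_a < 0:
        s2_a = 0.0
        truncated = True
    denom = s2_a + ms_w
    tau = s2_a / denom if denom > 0 else 1.0
    if ms_w == 0:
        f, p = np.inf, 0.0
    else:
        f = ms_a / ms_w
        p = float(stats.f.sf(f, a - 1, n - a))
    return RepeatabilityResult(
        tau=float(tau),
        se=None,
        p_value=p,
        n_groups=a,
        n0=float(n0),
        variance_among=float(s2_a),
        variance_within=float(ms_w),
        truncated=truncated,
    )


def _design_matrix(covariates: pd.DataFrame) -> np.ndarray:
    """Intercept + numeric columns as-is + dummy-coded categoricals."""
    parts = [np.ones((len(covariates), 1))]
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.to_numpy(dtype=float).reshape(-1, 1))
        else:
            d = pd.get_dummies(s, drop_first=True)
            parts.append(d.to_numpy(dtype=float))
    X = np.hstack(parts)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design matrix is rank deficient")
    return X


def adjusted_repeatability(
    values,
    group_ids,
    covariates: pd.DataFrame,
    bootstrap: int = 1000,
    seed=None,
) -> RepeatabilityResult:
    """Repeatability after OLS adjustment for fixed effects.

    ``covariates`` is a data frame aligned with ``values``; numeric columns
    enter linearly, non-numeric columns are dummy-coded.  The SE is the
    cluster-bootstrap (over individuals) standard deviation of τ; set
    ``bootstrap=0`` to skip it.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(group_ids)
    covariates = pd.DataFrame(covariates).reset_index(drop=True)
    if len(covariates) != y.size:
        raise ValueError("covariates must align with values")
    X = _design_matrix(covariates)

    def estimate(idx) -> RepeatabilityResult:
        Xi, yi, gi = X[idx], y[idx], g[idx]
        beta, _, rank, _ = np.linalg.lstsq(Xi, yi, rcond=None)
        resid = yi - Xi @ beta
        return repeatability_anova(resid, gi)

    base = estimate(np.arange(y.size))
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        labels = np.unique(g)
        members = {lab: np.flatnonzero(g == lab) for lab in labels}
        taus = []
        for _ in range(bootstrap):
            pick = rng.choice(labels, size=labels.size, replace=True)
            idx = np.concatenate([members[lab] for lab in pick])
            try:
                taus.append(estimate(idx).tau)
            except (ValueError, np.linalg.LinAlgError):
                continue
        if len(taus) > 1:
            base.se = float(np.std(taus, ddof=1))
        else:
            warnings.warn("bootstrap produced too few valid resamples", stacklevel=2)
    return base
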