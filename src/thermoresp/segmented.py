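"""Continuous segmented (piecewise-linear) least-squares regression.

The Scholander–Irving model of endotherm thermoregulation is a continuous
piecewise-linear response of metabolic rate (or body temperature,
evaporative heat loss, EHL/MR) to ambient temperature, with one or two
breakpoints and, typically, a horizontal plateau segment.  This module
implements the general fitting machinery:

* :class:`SegmentedRegression` — model object holding the data and the
  requested shape (number of breakpoints, per-segment slope constraints);
  its :meth:`~SegmentedRegression.fit` performs an exact profiled
  least-squares search over breakpoint locations (dense grid over the
  midpoints between consecutive sorted unique x values, refined by bounded
  scalar minimisation to 1e-4) and returns a
* :class:`SegmentedResults` — breakpoints with bootstrap standard errors,
  per-segment slopes and intercepts, fit statistics, prediction and a
  text ``summary()``.

For fixed breakpoints the model is linear: with segment j spanning
[L_j, U_j] the mean is  f(x) = a + Σ_j s_j · (clip(x, L_j, U_j) − L_j),
which is continuous by construction; a horizontal constraint on segment j
simply omits its column.  Profiling the linear parameters out leaves a
low-dimensional breakpoint search, exhaustive up to the grid resolution.

``select_model_type`` chooses among candidate shapes by nested F-tests,
preferring the simpler model unless the richer one fits significantly
better (alpha = 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = ["SegmentedRegression", "SegmentedResults", "select_model_type"]

_HORIZONTAL = "horizontal"
_FREE = "free"


def _design(x: np.ndarray, breakpoints: np.ndarray, constraints: tuple[str, ...]):
    """Design matrix of the continuous piecewise-linear model at fixed breaks."""
    lo = np.concatenate(([x.min()], breakpoints))
    hi = np.concatenate((breakpoints, [x.max()]))
    cols = [np.ones_like(x)]
    for j, c in enumerate(constraints):
        if c == _FREE:
            cols.append(np.clip(x, lo[j], hi[j]) - lo[j])
    return np.column_stack(cols)


def _sse_at(x, y, breakpoints, constraints):
    X = _design(x, np.asarray(breakpoints, dtype=float), constraints)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), beta


@dataclass
class SegmentedResults:
    """Fitted continuous piecewise-linear model.

    Attributes
    ----------
    breakpoints : ndarray
        Estimated breakpoint locations (x units), strictly increasing.
    breakpoint_se : ndarray or None
        Cluster-bootstrap standard errors (None when bootstrap was off).
    slopes : ndarray
        Slope of each segment in response units per x unit; exactly 0 for
        horizontal-constrained segments.
    intercepts : ndarray
        Per-segment intercepts such that y = slopes[j]*x + intercepts[j]
        within segment j; adjacent segments agree at each breakpoint.
    """

    model: "SegmentedRegression"
    breakpoints: np.ndarray
    slopes: np.ndarray
    intercepts: np.ndarray
    params: np.ndarray
    sse: float
    r2: float
    residual_sd: float
    nobs: int
    df_model: int
    breakpoint_se: np.ndarray | None = None
    slope_se: np.ndarray | None = None
    boot_breakpoints: np.ndarray | None = None
    boot_slopes: np.ndarray | None = None
    boot_intercepts: np.ndarray | None = None
    n_boot: int = 0

    @property
    def n_breakpoints(self) -> int:
        return len(self.breakpoints)

    @property
    def constraints(self) -> tuple[str, ...]:
        return self.model.constraints

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        edges = np.concatenate(
            ([-np.inf], self.breakpoints, [np.inf])
        )
        seg = np.searchsorted(edges, x, side="right") - 1
        seg = np.clip(seg, 0, len(self.slopes) - 1)
        return self.slopes[seg] * x + self.intercepts[seg]

    def segment_value(self, j: int, x: float) -> float:
        """Fitted value of segment j extended to x (used for plateau levels)."""
        return float(self.slopes[j] * x + self.intercepts[j])

    def plateau_level(self) -> float:
        """Level of the first horizontal segment (error if none is horizontal)."""
        for j, c in enumerate(self.constraints):
            if c == _HORIZONTAL:
                return float(self.intercepts[j])
        raise ValueError("model has no horizontal segment")

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else [None if np.isnan(v) else float(v) for v in a]

        return {
            "n_breakpoints": self.n_breakpoints,
            "breakpoints": arr(self.breakpoints),
            "breakpoint_se": arr(self.breakpoint_se),
            "slopes": arr(self.slopes),
            "slope_se": arr(self.slope_se),
            "intercepts": arr(self.intercepts),
            "constraints": list(self.constraints),
            "sse": self.sse,
            "r2": self.r2,
            "residual_sd": self.residual_sd,
            "n_obs": self.nobs,
        }

    def summary(self) -> str:
        lines = [
            "Segmented linear regression",
            "=" * 46,
            f"observations        {self.nobs}",
            f"breakpoints         {self.n_breakpoints}",
            f"R-squared           {self.r2:.4f}",
            f"residual SD         {self.residual_sd:.4g}",
        ]
        for k, b in enumerate(self.breakpoints):
            se = (
                f" +/- {self.breakpoint_se[k]:.3g}"
                if self.breakpoint_se is not None
                else ""
            )
            lines.append(f"breakpoint {k + 1}        {b:.4f}{se}")
        for j, (s, c) in enumerate(zip(self.slopes, self.constraints)):
            tag = " (horizontal)" if c == _HORIZONTAL else ""
            lines.append(f"segment {j + 1} slope     {s:.5g}{tag}")
        return "\n".join(lines)


class SegmentedRegression:
    """Continuous piecewise-linear least squares with 0-2 breakpoints.

    Parameters
    ----------
    endog : array-like
        Response values.
    exog : array-like
        Single predictor (e.g. ambient temperature, °C).
    n_breakpoints : int
        0, 1 or 2 breakpoints.
    constraints : sequence of {"free", "horizontal"}, optional
        One entry per segment (``n_breakpoints + 1``); horizontal pins the
        segment slope to exactly 0.  Default: all free.
    groups : array-like, optional
        Cluster labels (e.g. bird identity) for the bootstrap; resampling
        is then over clusters to respect repeated measures.
    min_per_segment : int
        Minimum observations required in each prospective segment
        (default 5).
    """

    def __init__(
        self,
        endog,
        exog,
        n_breakpoints: int = 1,
        constraints=None,
        groups=None,
        min_per_segment: int = 5,
    ):
        y = np.asarray(endog, dtype=float)
        x = np.asarray(exog, dtype=float)
        if x.ndim != 1 or y.shape != x.shape:
            raise ValueError("endog and exog must be 1-D arrays of equal length")
        mask = np.isfinite(x) & np.isfinite(y)
        self.exog = x[mask]
        self.endog = y[mask]
        if groups is not None:
            self.groups = np.asarray(groups)[mask]
        else:
            self.groups = None
        if n_breakpoints not in (0, 1, 2):
            raise ValueError("n_breakpoints must be 0, 1 or 2")
        self.n_breakpoints = n_breakpoints
        if constraints is None:
            constraints = (_FREE,) * (n_breakpoints + 1)
        constraints = tuple(constraints)
        if len(constraints) != n_breakpoints + 1:
            raise ValueError("need one constraint per segment")
        for c in constraints:
            if c not in (_FREE, _HORIZONTAL):
                raise ValueError(f"unknown constraint {c!r}")
        self.constraints = constraints
        self.min_per_segment = min_per_segment
        if np.unique(self.exog).size < 2:
            raise ValueError("exog values are all equal")
        n_seg = n_breakpoints + 1
        if self.endog.size < min_per_segment * n_seg:
            raise ValueError(
                f"need at least {min_per_segment} observations per prospective "
                f"segment ({min_per_segment * n_seg} total), got {self.endog.size}"
            )

    # ------------------------------------------------------------------ fit

    def _candidate_grid(self, x: np.ndarray) -> np.ndarray:
        """Midpoints between consecutive sorted unique x (plus the interior
        unique x themselves, so exact data-point knots are attainable),
        leaving at least two observations on each side."""
        ux = np.unique(x)
        mids = 0.5 * (ux[:-1] + ux[1:])
        cand = np.unique(np.concatenate((mids, ux[1:-1])))
        xs = np.sort(x)
        keep = []
        for m in cand:
            left = np.searchsorted(xs, m, side="left")
            right = x.size - np.searchsorted(xs, m, side="right")
            if left >= 2 and right >= 2:
                keep.append(m)
        return np.asarray(keep)

    def _refine_1d(self, x, y, k, bks, lo, hi):
        """Bounded scalar refinement of breakpoint k within (lo, hi)."""

        def f(b):
            trial = bks.copy()
            trial[k] = b
            if not np.all(np.diff(np.concatenate(([x.min()], trial, [x.max()]))) > 0):
                return np.inf
            return _sse_at(x, y, trial, self.constraints)[0]

        if hi - lo < 1e-10:
            return bks[k]
        res = optimize.minimize_scalar(
            f, bounds=(lo, hi), method="bounded", options={"xatol": 1e-4}
        )
        return float(res.x) if res.fun <= f(bks[k]) else bks[k]

    def _bracket(self, ux, b):
        """Data interval (consecutive unique-x pair) containing midpoint b."""
        i = np.searchsorted(ux, b) - 1
        i = np.clip(i, 0, len(ux) - 2)
        return ux[i], ux[i + 1]

    def _fit_breakpoints(self, x, y):
        grid = self._candidate_grid(x)
        k = self.n_breakpoints
        if k == 0:
            sse, beta = _sse_at(x, y, np.empty(0), self.constraints)
            return np.empty(0), sse, beta
        if grid.size < k:
            raise ValueError("too few distinct x values to place breakpoints")
        ux = np.unique(x)
        if k == 1:
            # SSE(b) is smooth within each data interval but only
            # piecewise-smooth globally and can hold several local minima,
            # so every admissible interval is polished
            best = np.inf
            best_b = grid[0]
            brackets = {self._bracket(ux, b) for b in grid}
            for lo, hi in sorted(brackets):
                mid = 0.5 * (lo + hi)
                b = self._refine_1d(x, y, 0, np.array([mid]), lo, hi)
                for cand in (b, mid, lo, hi):
                    if not grid.min() <= cand <= grid.max():
                        continue
                    s = _sse_at(x, y, [cand], self.constraints)[0]
                    if s < best - 1e-12:
                        best, best_b = s, cand
            bks = np.array([best_b])
        else:
            pairs = [
                (b1, b2)
                for i, b1 in enumerate(grid)
                for b2 in grid[i + 1 :]
                if np.count_nonzero((x > b1) & (x < b2)) >= 2
            ]
            if not pairs:
                raise ValueError("no admissible breakpoint pair")
            sses = np.array(
                [_sse_at(x, y, pair, self.constraints)[0] for pair in pairs]
            )
            bks = np.array(pairs[int(np.argmin(sses))])
            for _ in range(3):  # coordinate-wise polish
                for kk in (0, 1):
                    lo, hi = self._bracket(ux, bks[kk])
                    if kk == 0:
                        hi = min(hi, bks[1] - 1e-9)
                    else:
                        lo = max(lo, bks[0] + 1e-9)
                    bks[kk] = self._refine_1d(x, y, kk, bks, lo, hi)
        sse, beta = _sse_at(x, y, bks, self.constraints)
        return bks, sse, beta

    def _unpack(self, x, breakpoints, beta):
        """Per-segment (slope, intercept) from the profiled parameters."""
        n_seg = self.n_breakpoints + 1
        slopes = np.zeros(n_seg)
        i = 1
        for j, c in enumerate(self.constraints):
            if c == _FREE:
                slopes[j] = beta[i]
                i += 1
        lo = np.concatenate(([x.min()], breakpoints))
        intercepts = np.zeros(n_seg)
        level = beta[0]  # fitted value at x.min()
        for j in range(n_seg):
            intercepts[j] = level - slopes[j] * lo[j]
            if j < self.n_breakpoints:
                level = slopes[j] * breakpoints[j] + intercepts[j]
        return slopes, intercepts

    def fit(self, bootstrap: int = 0, seed=None) -> SegmentedResults:
        """Fit; with ``bootstrap > 0`` also compute resampling SEs.

        Bootstrap resamples clusters (``groups``) with replacement when
        cluster labels were given, otherwise rows.
        """
        x, y = self.exog, self.endog
        bks, sse, beta = self._fit_breakpoints(x, y)
        slopes, intercepts = self._unpack(x, bks, beta)
        sst = float(np.sum((y - y.mean()) ** 2))
        n = y.size
        # one parameter per breakpoint, per free slope, plus the intercept
        df_model = self.n_breakpoints + int(beta.size)
        dof = max(n - df_model, 1)
        res = SegmentedResults(
            model=self,
            breakpoints=bks,
            slopes=slopes,
            intercepts=intercepts,
            params=beta,
            sse=sse,
            r2=1.0 - sse / sst if sst > 0 else 1.0,
            residual_sd=float(np.sqrt(sse / dof)),
            nobs=n,
            df_model=df_model,
        )
        if bootstrap > 0:
            self._bootstrap(res, bootstrap, seed)
        return res

    def _bootstrap(self, res: SegmentedResults, n_boot: int, seed) -> None:
        rng = np.random.default_rng(seed)
        x, y = self.exog, self.endog
        if self.groups is not None:
            labels = np.unique(self.groups)
            members = {g: np.flatnonzero(self.groups == g) for g in labels}
        bb = np.full((n_boot, self.n_breakpoints), np.nan)
        bs = np.full((n_boot, self.n_breakpoints + 1), np.nan)
        bi = np.full((n_boot, self.n_breakpoints + 1), np.nan)
        for b in range(n_boot):
            if self.groups is not None:
                pick = rng.choice(labels, size=labels.size, replace=True)
                idx = np.concatenate([members[g] for g in pick])
            else:
                idx = rng.integers(0, x.size, size=x.size)
            try:
                bk, _, beta = self._fit_breakpoints(x[idx], y[idx])
                bb[b] = bk
                bs[b], bi[b] = self._unpack(x[idx], bk, beta)
            except (ValueError, np.linalg.LinAlgError):
                continue  # degenerate resample; left as NaN
        ok = np.isfinite(bb).all(axis=1)
        if ok.sum() < n_boot:
            warnings.warn(
                f"{n_boot - int(ok.sum())} of {n_boot} bootstrap resamples "
                "were degenerate and were dropped",
                stacklevel=2,
            )
        res.boot_breakpoints = bb
        res.boot_slopes = bs
        res.boot_intercepts = bi
        res.breakpoint_se = np.nanstd(bb, axis=0, ddof=1) if ok.any() else None
        res.slope_se = np.nanstd(bs, axis=0, ddof=1) if ok.any() else None
        res.n_boot = int(ok.sum())


def select_model_type(
    x, y, candidates, alpha: float = 0.05, groups=None
) -> SegmentedResults:
    """Choose among candidate segmented shapes by nested F-tests.

    ``candidates`` is an iterable of ``(n_breakpoints, constraints)`` pairs
    (constraints may be None for all-free).  Candidates are ordered by
    model degrees of freedom; a richer model replaces the current choice
    only when the extra-sum-of-squares F-test is significant at ``alpha``.
    """
    cands = list(candidates)
    if not cands:
        raise ValueError("candidate set is empty")
    fits = []
    for nb, cons in cands:
        m = SegmentedRegression(y, x, n_breakpoints=nb, constraints=cons, groups=groups)
        fits.append(m.fit())
    fits.sort(key=lambda r: r.df_model)
    best = fits[0]
    n = best.nobs
    for cand in fits[1:]:
        d = cand.df_model - best.df_model
        if d <= 0 or cand.sse >= best.sse:
            continue
        dof = n - cand.df_model
        f = ((best.sse - cand.sse) / d) / (cand.sse / dof)
        p = stats.f.sf(f, d, dof)
        if p < alpha:
            best = cand
    return best
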