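"""Scholander–Irving thermoregulatory profile from steady-state data.

Fits the four canonical responses of a resting endotherm to ambient
temperature T_a and assembles the derived physiology:

* metabolic rate (MR, W): three segments — a falling limb below the
  thermoneutral zone, a horizontal plateau (basal metabolic rate) between
  the lower and upper critical temperatures T_LC and T_UC, and a rising
  limb above T_UC;
* body temperature (T_b, °C): horizontal plateau, then a rising limb
  above the hyperthermia threshold;
* evaporative heat loss (EHL, W): horizontal plateau, then a rising limb
  above the EHL inflection;
* evaporative cooling efficiency (EHL/MR): fitted directly on the
  per-observation ratio, same two-segment shape.

Birds are pooled across individuals; the breakpoint standard errors come
from a cluster bootstrap that resamples birds, respecting the repeated
measurements of each individual.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .segmented import SegmentedRegression, SegmentedResults

__all__ = ["ThermoregProfile", "ScholanderModel", "ScholanderResults", "derive_profile"]

#: response name -> (column, n_breakpoints, constraints)
RESPONSE_SHAPES = {
    "mr": ("mr_w", 2, ("free", "horizontal", "free")),
    "tb": ("tb_c", 1, ("horizontal", "free")),
    "ehl": ("ehl_w", 1, ("horizontal", "free")),
    "ehlmr": ("ehlmr", 1, ("horizontal", "free")),
}


@dataclass
class ThermoregProfile:
    """Derived thermoregulatory physiology of the fitted profile."""

    t_lc: float  # lower critical temperature, °C
    t_uc: float  # upper critical temperature, °C
    bmr: float  # basal metabolic rate (TNZ plateau), W
    mr_slope_below: float  # W per °C, below T_LC (negative going up in T_a)
    mr_slope_above: float  # W per °C, above T_UC
    tb_plateau: float  # normothermic body temperature, °C
    tb_threshold: float  # T_a at onset of regulated hyperthermia, °C
    tb_slope: float  # °C of T_b per °C of T_a above threshold
    ehl_plateau: float  # minimal evaporative heat loss, W
    ehl_inflection: float  # T_a at the EHL inflection, °C
    ehl_slope: float  # W per °C above the inflection
    ehlmr_inflection: float  # T_a at the EHL/MR inflection, °C
    ehlmr_max: float  # fitted EHL/MR at the highest observed T_a
    t_lc_se: float | None = None
    t_uc_se: float | None = None
    bmr_se: float | None = None
    tb_threshold_se: float | None = None
    ehl_inflection_se: float | None = None

    def __post_init__(self) -> None:
        if not self.t_lc < self.t_uc:
            raise ValueError("lower critical temperature must lie below the upper")
        if self.ehl_plateau <= 0:
            raise ValueError("EHL plateau must be positive")

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = None if v is None or not np.isfinite(v) else float(v)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ThermoregProfile":
        names = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in names})


def derive_profile(fits: dict[str, SegmentedResults], x_max=None) -> ThermoregProfile:
    """Assemble a :class:`ThermoregProfile` from the four response fits.

    Requires the canonical shapes: the MR fit must have two breakpoints
    with a horizontal middle segment; the T_b, EHL and EHL/MR fits one
    breakpoint with a horizontal first segment.
    """
    for name in ("mr", "tb", "ehl", "ehlmr"):
        if name not in fits:
            raise ValueError(f"missing fit for response {name!r}")
    mr = fits["mr"]
    if mr.n_breakpoints != 2 or mr.constraints[1] != "horizontal":
        raise ValueError(
            "mr fit must have 2 breakpoints with a horizontal middle segment"
        )
    for name in ("tb", "ehl", "ehlmr"):
        f = fits[name]
        if f.n_breakpoints != 1 or f.constraints[0] != "horizontal":
            raise ValueError(
                f"{name} fit must have 1 breakpoint with a horizontal first segment"
            )
    tb, ehl, ehlmr = fits["tb"], fits["ehl"], fits["ehlmr"]
    if x_max is None:
        x_max = float(ehlmr.model.exog.max())

    def se(res, k):
        return None if res.breakpoint_se is None else float(res.breakpoint_se[k])

    # plateau SE is attached by ScholanderModel when bootstrap was requested
    bmr_se = getattr(mr, "plateau_se", None)
    return ThermoregProfile(
        t_lc=float(mr.breakpoints[0]),
        t_uc=float(mr.breakpoints[1]),
        bmr=mr.plateau_level(),
        mr_slope_below=float(mr.slopes[0]),
        mr_slope_above=float(mr.slopes[2]),
        tb_plateau=tb.plateau_level(),
        tb_threshold=float(tb.breakpoints[0]),
        tb_slope=float(tb.slopes[1]),
        ehl_plateau=ehl.plateau_level(),
        ehl_inflection=float(ehl.breakpoints[0]),
        ehl_slope=float(ehl.slopes[1]),
        ehlmr_inflection=float(ehlmr.breakpoints[0]),
        ehlmr_max=float(ehlmr.predict(x_max)),
        t_lc_se=se(mr, 0),
        t_uc_se=se(mr, 1),
        bmr_se=bmr_se,
        tb_threshold_se=se(tb, 0),
        ehl_inflection_se=se(ehl, 0),
    )


class ScholanderModel:
    """Thermoregulatory profile model over a steady-state table.

    Parameters
    ----------
    data : pandas.DataFrame
        Steady-state table with at least ``ta_c`` plus the response columns
        ``mr_w``, ``tb_c``, ``ehl_w`` (``ehlmr`` is computed as
        ``ehl_w / mr_w`` when absent) and, for the cluster bootstrap,
        ``bird_id``.
    responses : sequence of str
        Which responses to fit; default all four.
    """

    def __init__(self, data: pd.DataFrame, responses=("mr", "tb", "ehl", "ehlmr")):
        data = data.copy()
        if (
            "ehlmr" in responses
            and "ehlmr" not in data.columns
            and {"ehl_w", "mr_w"} <= set(data.columns)
        ):
            data["ehlmr"] = data["ehl_w"] / data["mr_w"]
        for r in responses:
            if r not in RESPONSE_SHAPES:
                raise ValueError(f"unknown response {r!r}")
            col = RESPONSE_SHAPES[r][0]
            if col not in data.columns:
                raise ValueError(f"data lacks column {col!r} for response {r!r}")
        if "ta_c" not in data.columns:
            raise ValueError("data lacks column 'ta_c'")
        self.data = data
        self.responses = tuple(responses)

    @classmethod
    def from_dataframe(cls, data, **kw) -> "ScholanderModel":
        return cls(data, **kw)

    @classmethod
    def from_csv(cls, path, **kw) -> "ScholanderModel":
        from .io import read_steady_state

        return cls(read_steady_state(path), **kw)

    def fit(self, bootstrap: int = 0, seed=None) -> "ScholanderResults":
        """Fit every requested response; ``bootstrap`` resamples birds."""
        has_birds = "bird_id" in self.data.columns
        rng = np.random.default_rng(seed)
        fits: dict[str, SegmentedResults] = {}
        for r in self.responses:
            col, nb, cons = RESPONSE_SHAPES[r]
            sub = self.data.dropna(subset=[col, "ta_c"])
            g = sub["bird_id"].to_numpy() if has_birds else None
            # independent child seed per response keeps fits reproducible
            # regardless of which responses are requested
            sub_seed = int(rng.integers(2**31 - 1))
            m = SegmentedRegression(
                sub[col].to_numpy(),
                sub["ta_c"].to_numpy(),
                n_breakpoints=nb,
                constraints=cons,
                groups=g,
            )
            fits[r] = m.fit(bootstrap=bootstrap, seed=sub_seed)
        profile = None
        if set(self.responses) == set(RESPONSE_SHAPES):
            if fits["mr"].boot_breakpoints is not None:
                self._attach_plateau_se(fits["mr"])
            profile = derive_profile(fits, x_max=float(self.data["ta_c"].max()))
        return ScholanderResults(self, fits, profile)

    @staticmethod
    def _attach_plateau_se(mr_fit: SegmentedResults) -> None:
        """Bootstrap SE of the BMR plateau (intercept of the horizontal
        middle segment) from the stored per-resample intercepts."""
        levels = mr_fit.boot_intercepts[:, 1]
        levels = levels[np.isfinite(levels)]
        mr_fit.plateau_se = (
            float(np.std(levels, ddof=1)) if levels.size > 1 else None
        )


class ScholanderResults:
    """Fitted thermoregulatory profile: per-response fits plus the profile."""

    def __init__(self, model, fits, profile):
        self.model = model
        self.fits = fits
        self.profile = profile

    def summary(self) -> str:
        lines = ["Scholander-Irving thermoregulatory profile", "=" * 46]
        p = self.profile
        if p is not None:
            def fmt(v, se):
                s = f"{v:.4g}"
                if se is not None:
                    s += f" +/- {se:.2g}"
                return s

            lines += [
                f"T_LC (°C)            {fmt(p.t_lc, p.t_lc_se)}",
                f"T_UC (°C)            {fmt(p.t_uc, p.t_uc_se)}",
                f"BMR (W)              {fmt(p.bmr, p.bmr_se)}",
                f"MR slope < T_LC      {p.mr_slope_below:.4g} W/°C",
                f"MR slope > T_UC      {p.mr_slope_above:.4g} W/°C",
                f"T_b plateau (°C)     {p.tb_plateau:.4g}",
                f"T_b threshold (°C)   {fmt(p.tb_threshold, p.tb_threshold_se)}",
                f"T_b slope            {p.tb_slope:.3g} °C/°C",
                f"EHL plateau (W)      {p.ehl_plateau:.3g}",
                f"EHL inflection (°C)  {fmt(p.ehl_inflection, p.ehl_inflection_se)}",
                f"EHL slope            {p.ehl_slope:.3g} W/°C",
                f"EHL/MR inflection    {p.ehlmr_inflection:.4g} °C",
                f"EHL/MR at max T_a    {p.ehlmr_max:.3g}",
            ]
        for name, fit in self.fits.items():
            lines += ["", f"-- {name} --", fit.summary()]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Diagnostic panel: data and fitted piecewise lines per response."""
        import matplotlib.pyplot as plt

        names = list(self.fits)
        fig, axes = plt.subplots(
            len(names), 1, figsize=(6, 2.6 * len(names)), sharex=True
        )
        axes = np.atleast_1d(axes)
        for axis, name in zip(axes, names):
            fit = self.fits[name]
            x = fit.model.exog
            axis.plot(x, fit.model.endog, ".", ms=3, alpha=0.5)
            xs = np.linspace(x.min(), x.max(), 400)
            axis.plot(xs, fit.predict(xs), "-", lw=1.5)
            for b in fit.breakpoints:
                axis.axvline(b, ls=":", lw=0.8, color="grey")
            axis.set_ylabel(name)
        axes[-1].set_xlabel("ambient temperature (°C)")
        fig.tight_layout()
        return fig
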