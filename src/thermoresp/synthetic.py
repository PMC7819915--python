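"""Synthetic respirometry data with known ground truth.

Emulates the study design the package is meant to analyse: 36 zebra
finches in four acclimation groups measured by flow-through respirometry
at ambient temperatures between 22 and 44 °C, each bird at two randomly
chosen temperatures per measurement day.  Three generators are provided:

* :func:`generate_steady_state` — one row per bird × T_a with metabolic
  rate, body temperature and evaporative heat loss drawn from piecewise
  Scholander–Irving truth curves plus among-individual and residual noise;
* :func:`generate_raw_trace` — a multiplexed analyzer time series (5-min
  channel dwells, periodic reference-air readings, optional affine drift
  and sensor noise) built with the forward steady-state mass balance;
* :func:`generate_mask_session` — two-line (head-mask + chamber) records
  for partitioning evaporative heat loss into respiratory and cutaneous
  avenues.

The forward model :func:`excurrent_sample` computes the analyzer readings
a given true (V̇O₂, V̇CO₂, EWL) would produce; it is the exact inverse
problem of :func:`thermoresp.calorimetry.gas_exchange_rates` and is
derived independently (species bookkeeping forward in time, rather than
solving the inversion), so the pair form a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .calorimetry import (
    GasSample,
    LATENT_HEAT_J_PER_MG,
    MG_H2O_PER_ML,
    STANDARD_BP_KPA,
)

__all__ = [
    "ScholanderTruth",
    "GeneratorConfig",
    "PartitionTruth",
    "excurrent_sample",
    "generate_steady_state",
    "generate_raw_trace",
    "generate_mask_session",
]


# --------------------------------------------------------------- forward model


def excurrent_sample(
    vo2: float,
    vco2: float,
    ewl: float,
    flow: float,
    mode: str = "push_chamber",
    fio2: float = 0.2095,
    fico2: float = 0.0,
    pih2o: float = 0.0,
    bp: float = STANDARD_BP_KPA,
) -> GasSample:
    """Forward steady-state mass balance: analyzer readings from true rates.

    ``flow`` is the metered flow of the configuration: wet incurrent for
    ``push_chamber``, dried excurrent for the pull modes.  All flows are
    ml min⁻¹ STP, EWL in mg min⁻¹.
    """
    vh2o = ewl / MG_H2O_PER_ML
    fih2o = pih2o / bp
    if mode == "push_chamber":
        fri = flow
        fred = fri * (1.0 - fih2o) - vo2 + vco2
    elif mode in ("pull_mask", "pull_chamber"):
        fred = flow
        fri = (fred + vo2 - vco2) / (1.0 - fih2o)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    feo2 = (fri * fio2 - vo2) / fred
    feco2 = (fri * fico2 + vco2) / fred
    water_out = vh2o + fri * fih2o
    fre = fred + water_out
    ph2o = bp * water_out / fre
    return GasSample(
        feo2=feo2,
        feco2=feco2,
        ph2o=ph2o,
        flow=flow,
        mode=mode,
        bp=bp,
        fio2=fio2,
        fico2=fico2,
        pih2o=pih2o,
    )


# ------------------------------------------------------------------- truths


@dataclass
class ScholanderTruth:
    """Ground-truth piecewise thermoregulatory curves.

    Defaults describe a ~15 g passerine: thermoneutral zone 34.87-37.47 °C
    around a 0.24 W basal rate, normothermic body temperature 40.98 °C with
    hyperthermia above T_a = 35.94 °C, and a 0.061 W evaporative plateau
    inflecting at 37.45 °C.
    """

    t_lc: float = 34.87  # °C
    t_uc: float = 37.47  # °C
    bmr: float = 0.24  # W
    mr_slope_below: float = 0.015  # W per °C of cooling below T_LC
    mr_slope_above: float = 0.013  # W per °C above T_UC
    tb_plateau: float = 40.98  # °C
    tb_threshold: float = 35.94  # °C
    tb_slope: float = 0.43  # °C per °C
    ehl_plateau: float = 0.061  # W
    ehl_inflection: float = 37.45  # °C
    ehl_slope: float = 0.045  # W per °C

    def __post_init__(self) -> None:
        if not self.t_lc < self.t_uc:
            raise ValueError("t_lc must be below t_uc")

    def mr_at(self, ta) -> np.ndarray:
        ta = np.asarray(ta, dtype=float)
        return (
            self.bmr
            + self.mr_slope_below * np.clip(self.t_lc - ta, 0.0, None)
            + self.mr_slope_above * np.clip(ta - self.t_uc, 0.0, None)
        )

    def tb_at(self, ta) -> np.ndarray:
        ta = np.asarray(ta, dtype=float)
        return self.tb_plateau + self.tb_slope * np.clip(ta - self.tb_threshold, 0.0, None)

    def ehl_at(self, ta) -> np.ndarray:
        ta = np.asarray(ta, dtype=float)
        return self.ehl_plateau + self.ehl_slope * np.clip(
            ta - self.ehl_inflection, 0.0, None
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d) -> "ScholanderTruth":
        return cls(**d)


GROUPS = ("23_adlib", "23_restricted", "40_adlib", "40_restricted")
#: group sizes of the emulated design (8 + 10 + 9 + 9 = 36)
GROUP_SIZES = (8, 10, 9, 9)


@dataclass
class GeneratorConfig:
    """Study-design and noise parameters of the steady-state generator.

    The residual and among-individual SDs put the true intraclass
    correlation of metabolic rate at 0.016²/(0.016²+0.020²) = 0.390.
    """

    n_birds: int = 36
    ta_min: float = 22.0  # °C
    ta_max: float = 44.0  # °C
    ta_step: float = 0.5  # °C grid resolution
    n_days: int = 6  # measurement days per bird
    ta_per_day: int = 2  # randomly chosen T_a's per bird per day
    scheme: str = "random_pairs"  # or "full_grid": every bird at every grid T_a
    noise_sd_mr: float = 0.020  # W, residual
    noise_sd_tb: float = 0.30  # °C, residual
    noise_sd_ehl: float = 0.008  # W, residual
    among_sd_mr: float = 0.016  # W, among-individual intercept SD
    among_sd_tb: float = 0.25  # °C
    among_sd_ehl: float = 0.0  # W
    mb_mean: float = 15.0  # g
    mb_sd: float = 1.0  # g
    rer_range: tuple = (0.75, 0.95)
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "noise_sd_mr",
            "noise_sd_tb",
            "noise_sd_ehl",
            "among_sd_mr",
            "among_sd_tb",
            "among_sd_ehl",
            "mb_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducible generation")
        if self.scheme not in ("random_pairs", "full_grid"):
            raise ValueError(f"unknown scheme {self.scheme!r}")

    @property
    def ta_grid(self) -> np.ndarray:
        n = int(round((self.ta_max - self.ta_min) / self.ta_step)) + 1
        return self.ta_min + self.ta_step * np.arange(n)


def _bird_ids(n: int) -> list[str]:
    return [f"bird{i + 1:02d}" for i in range(n)]


def _bird_groups(n: int) -> list[str]:
    out = []
    for g, size in zip(GROUPS, GROUP_SIZES):
        out.extend([g] * size)
    while len(out) < n:
        out.append(GROUPS[len(out) % len(GROUPS)])
    return out[:n]


def generate_steady_state(
    truth: ScholanderTruth | None = None, config: GeneratorConfig | None = None
) -> pd.DataFrame:
    """Steady-state table (one row per bird × T_a) with known truth.

    Noise is injected on MR, T_b and EHL; EWL, V̇O₂ and V̇CO₂ are then
    back-computed from the *noisy* MR and EHL so every row satisfies the
    calorimetry identities exactly (EHL = EWL·2.4/60,
    MR = V̇O₂·(16 + 5.164·RER)/60, RER = V̇CO₂/V̇O₂).
    """
    truth = truth or ScholanderTruth()
    config = config or GeneratorConfig(seed=0)
    rng = np.random.default_rng(config.seed)
    ids = _bird_ids(config.n_birds)
    groups = _bird_groups(config.n_birds)
    mb = rng.normal(config.mb_mean, config.mb_sd, size=config.n_birds)
    u_mr = rng.normal(0.0, config.among_sd_mr, size=config.n_birds)
    u_tb = rng.normal(0.0, config.among_sd_tb, size=config.n_birds)
    u_ehl = rng.normal(0.0, config.among_sd_ehl, size=config.n_birds)
    grid = config.ta_grid
    rows = []
    for i, bird in enumerate(ids):
        if config.scheme == "full_grid":
            tas = grid
        else:
            tas = np.concatenate(
                [
                    rng.choice(grid, size=min(config.ta_per_day, grid.size), replace=False)
                    for _ in range(config.n_days)
                ]
            )
        for ta in tas:
            mr = float(truth.mr_at(ta) + u_mr[i] + rng.normal(0, config.noise_sd_mr))
            tb = float(truth.tb_at(ta) + u_tb[i] + rng.normal(0, config.noise_sd_tb))
            ehl = float(
                truth.ehl_at(ta) + u_ehl[i] + rng.normal(0, config.noise_sd_ehl)
            )
            mr = max(mr, 1e-6)
            ehl = max(ehl, 0.0)
            rer = float(rng.uniform(*config.rer_range))
            vo2 = mr * 60.0 / (16.0 + 5.164 * rer)
            rows.append(
                {
                    "bird_id": bird,
                    "group": groups[i],
                    "acclimation": "initial",
                    "ta_c": float(ta),
                    "mb_g": float(mb[i]),
                    "vo2_mlmin": vo2,
                    "vco2_mlmin": rer * vo2,
                    "ewl_mgmin": ehl * 60.0 / LATENT_HEAT_J_PER_MG,
                    "mr_w": mr,
                    "ehl_w": ehl,
                    "tb_c": tb,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- raw traces


@dataclass
class TraceConfig:
    """Multiplexed-system layout and analyzer imperfections."""

    flow: float = 500.0  # ml min⁻¹ STP per chamber, pushed and metered upstream
    dwell_s: float = 300.0  # multiplexer dwell per channel
    animals_per_ref: int = 3  # animal dwells between reference readings (≤20 min)
    n_cycles: int = 3  # repetitions of the full channel rotation
    dt_s: float = 2.0  # 0.5 Hz acquisition
    drift_o2_per_s: float = 0.0  # affine analyzer drift on the O₂ fraction
    drift_co2_per_s: float = 0.0
    drift_ph2o_per_s: float = 0.0  # kPa s⁻¹
    noise_o2: float = 0.0  # Gaussian sensor SD on fractions / kPa
    noise_co2: float = 0.0
    noise_ph2o: float = 0.0
    ta_c: float = 30.0
    bp: float = STANDARD_BP_KPA
    seed: int | None = None


MAX_CHAMBERS = 10


def generate_raw_trace(rates: dict, config: TraceConfig | None = None):
    """Multiplexed analyzer trace for up to 10 chambers.

    ``rates`` maps channel id (int) to true ``(vo2, vco2, ewl)`` of the
    animal in that chamber.  The schedule interleaves a 5-min reference
    (channel ``REF``) every ``animals_per_ref`` animal dwells, so incurrent
    air is re-read at least every 20 minutes.  Returns ``(trace_df, truth)``
    where truth maps channel → the true rates.
    """
    config = config or TraceConfig(seed=0)
    if len(rates) > MAX_CHAMBERS:
        raise ValueError(f"at most {MAX_CHAMBERS} chambers supported, got {len(rates)}")
    rng = np.random.default_rng(config.seed)
    channels = list(rates)
    schedule: list[str | int] = []
    pending = channels * config.n_cycles
    while pending:
        schedule.append("REF")
        schedule.extend(pending[: config.animals_per_ref])
        pending = pending[config.animals_per_ref :]
    schedule.append("REF")

    n_per_dwell = int(round(config.dwell_s / config.dt_s))
    rows = []
    t = 0.0
    for ch in schedule:
        if ch == "REF":
            feo2, feco2, ph2o = 0.2095, 0.0, 0.0
        else:
            s = excurrent_sample(*rates[ch], flow=config.flow, mode="push_chamber", bp=config.bp)
            feo2, feco2, ph2o = s.feo2, s.feco2, s.ph2o
        for _ in range(n_per_dwell):
            rows.append(
                {
                    "time_s": t,
                    "channel": str(ch) if ch == "REF" else int(ch),
                    "feo2": feo2
                    + config.drift_o2_per_s * t
                    + rng.normal(0, config.noise_o2),
                    "feco2": feco2
                    + config.drift_co2_per_s * t
                    + rng.normal(0, config.noise_co2),
                    "ph2o_kpa": max(
                        ph2o
                        + config.drift_ph2o_per_s * t
                        + rng.normal(0, config.noise_ph2o),
                        0.0,
                    ),
                    "flow_mlmin": config.flow,
                    "ta_c": config.ta_c,
                }
            )
            t += config.dt_s
    return pd.DataFrame(rows), dict(rates)


# -------------------------------------------------------------- mask sessions


@dataclass
class PartitionTruth:
    """Mean respiratory/cutaneous water-loss truth per T_a stratum (mg min⁻¹).

    Defaults make the cutaneous avenue dominate at 25 °C (CEHL ≈ 61 % of
    the total) and the respiratory avenue dominate at 40 °C (CEHL ≈ 21 %),
    with mask-line metabolic rates typical of restrained birds.
    """

    rewl: dict = field(default_factory=lambda: {25.0: 0.98, 40.0: 7.4})
    cewl: dict = field(default_factory=lambda: {25.0: 1.53, 40.0: 1.91})
    vo2: dict = field(default_factory=lambda: {25.0: 1.10, 40.0: 1.05})
    rer: float = 0.85
    cv: float = 0.20  # lognormal among-bird coefficient of variation


@dataclass
class MaskConfig:
    n_birds: int = 36
    mask_flow: float = 500.0  # ml min⁻¹, pulled through the mask, metered dry
    chamber_flow: float = 200.0  # ml min⁻¹, pulled from the chamber
    bp: float = STANDARD_BP_KPA
    seed: int | None = None


def generate_mask_session(
    truth: PartitionTruth | None = None, config: MaskConfig | None = None
):
    """Two-line mask-session table with known per-record truth.

    Returns ``(session_df, truth_df)``: one mask-line and one chamber-line
    record per bird per T_a stratum, plus the true (REWL, CEWL) of each.
    """
    truth = truth or PartitionTruth()
    config = config or MaskConfig(seed=0)
    rng = np.random.default_rng(config.seed)
    sigma = np.sqrt(np.log(1.0 + truth.cv**2))
    rows, truths = [], []
    for i in range(config.n_birds):
        bird = f"bird{i + 1:02d}"
        for ta in sorted(truth.rewl):
            rewl = truth.rewl[ta] * rng.lognormal(-0.5 * sigma**2, sigma)
            cewl = truth.cewl[ta] * rng.lognormal(-0.5 * sigma**2, sigma)
            vo2 = truth.vo2[ta] * rng.lognormal(-0.5 * sigma**2, sigma)
            mask = excurrent_sample(
                vo2, truth.rer * vo2, rewl, flow=config.mask_flow, mode="pull_mask",
                bp=config.bp,
            )
            chamber = excurrent_sample(
                0.0, 0.0, cewl, flow=config.chamber_flow, mode="pull_chamber",
                bp=config.bp,
            )
            for line, s in (("mask", mask), ("chamber", chamber)):
                rows.append(
                    {
                        "bird_id": bird,
                        "ta_set_c": ta,
                        "line": line,
                        "feo2": s.feo2,
                        "feco2": s.feco2,
                        "ph2o_kpa": s.ph2o,
                        "bp_kpa": s.bp,
                        "flow_mlmin": s.flow,
                    }
                )
            truths.append(
                {"bird_id": bird, "ta_set_c": ta, "rewl": rewl, "cewl": cewl, "vo2": vo2}
            )
    return pd.DataFrame(rows), pd.DataFrame(truths)
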