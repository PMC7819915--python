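"""Gas-exchange calorimetry: converting analyzer readings into physiological rates.

Flow-through (open-flow) respirometry infers an animal's oxygen consumption
(V̇O₂), carbon-dioxide production (V̇CO₂) and evaporative water loss (EWL)
from the difference between incurrent and excurrent air composition at a
known flow rate.  This module holds the steady-state mass-balance inversions
for the three plumbing configurations supported:

``push_chamber``
    Dry, CO₂-scrubbed air is pushed through the chamber; flow is metered
    *upstream* on the incurrent stream.
``pull_mask`` / ``pull_chamber``
    Air is pulled through a head mask or chamber; flow is metered
    *downstream*, after the subsample has been dried.

Analyzer conventions follow the usual instrument chain: water-vapour
pressure is read on the wet stream (so the water fraction is P_H2O/BP),
while O₂ and CO₂ fractions are read after drying and are therefore
*dry-basis* fractions of the dried stream.

Derivation (documented here because the inversion is exact, not an
approximation).  Write FRi for the wet incurrent flow, FRe for the wet
excurrent flow and FRed for the dried excurrent flow (all ml min⁻¹ STP).
Only N₂ (plus inert trace gases) passes through the animal unchanged, so

    FRi · (1 − FiO₂ − FiCO₂ − FiH₂O) = FRed · (1 − FeO₂ − FeCO₂)

links the metered flow to the unknown one in either direction.  Then

    V̇O₂  = FRi·FiO₂  − FRed·FeO₂
    V̇CO₂ = FRed·FeCO₂ − FRi·FiCO₂
    FRe  = FRed / (1 − FeH₂O)
    V̇H₂O = FRe·FeH₂O − FRi·FiH₂O

with EWL (mg min⁻¹) = 0.803 · V̇H₂O, where 0.803 mg ml⁻¹ is the STP density
of water vapour (18.015 g mol⁻¹ / 22.414 l mol⁻¹).

Downstream conversions: the oxyjoule equivalent (16 + 5.164·RER) J per ml
O₂ turns V̇O₂ into metabolic rate in watts; the latent heat of vaporization
2.4 J mg⁻¹ turns EWL into evaporative heat loss; dry thermal conductance is
(MR − EHL)/((T_b − T_a)·A_s) with surface area A_s = 10·m_b^0.667 cm².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GasSample",
    "GasExchangeRates",
    "MetabolicPoint",
    "gas_exchange_rates",
    "respiratory_exchange_ratio",
    "metabolic_rate",
    "ehl_from_ewl",
    "surface_area",
    "thermal_conductance",
    "MG_H2O_PER_ML",
    "LATENT_HEAT_J_PER_MG",
    "STANDARD_BP_KPA",
]

#: mg of water per ml of water vapour at STP (18.015 g mol-1 / 22.414 l mol-1)
MG_H2O_PER_ML = 0.803
#: latent heat of vaporization of water, J per mg
LATENT_HEAT_J_PER_MG = 2.4
#: default barometric pressure, kPa
STANDARD_BP_KPA = 101.325

MODES = ("push_chamber", "pull_mask", "pull_chamber")

#: chamber runs are only valid while water vapour stays below this pressure
MAX_CHAMBER_PH2O_KPA = 2.5


@dataclass
class GasSample:
    """One steady-state analyzer reading of an excurrent airstream.

    Parameters
    ----------
    feo2, feco2 : float
        Dry-basis fractional O₂ / CO₂ concentration of the dried excurrent
        subsample (dimensionless, 0-1).
    ph2o : float
        Water-vapour partial pressure of the wet excurrent stream, kPa.
    bp : float
        Barometric pressure, kPa.
    flow : float
        Metered flow, ml min⁻¹ STP.  Incurrent for ``push_chamber``;
        dried excurrent for the pull modes.
    mode : str
        One of ``push_chamber``, ``pull_mask``, ``pull_chamber``.
    fio2, fico2, pih2o : float
        Incurrent composition; defaults are dry CO₂-free atmospheric air.
    """

    feo2: float
    feco2: float
    ph2o: float
    flow: float
    mode: str = "push_chamber"
    bp: float = STANDARD_BP_KPA
    fio2: float = 0.2095
    fico2: float = 0.0
    pih2o: float = 0.0

    def __post_init__(self) -> None:
        for name in ("feo2", "feco2", "fio2", "fico2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} outside [0, 1]")
        if self.flow <= 0:
            raise ValueError(f"flow must be positive, got {self.flow!r}")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.ph2o >= self.bp:
            raise ValueError(
                f"ph2o={self.ph2o} kPa must be below barometric pressure {self.bp} kPa"
            )
        if self.pih2o >= self.bp:
            raise ValueError("incurrent pih2o must be below barometric pressure")
        if self.ph2o < 0 or self.pih2o < 0:
            raise ValueError("water-vapour pressures must be non-negative")


@dataclass
class GasExchangeRates:
    """Inverted physiological rates for one :class:`GasSample`."""

    vo2: float  # ml O2 min-1 STP
    vco2: float  # ml CO2 min-1 STP
    ewl: float  # mg H2O min-1
    flagged: bool = False  # True when a rate was non-physically negative

    def __iter__(self):
        return iter((self.vo2, self.vco2, self.ewl))


@dataclass
class MetabolicPoint:
    """One steady-state observation of a bird at one ambient temperature."""

    vo2: float
    vco2: float
    rer: float
    ewl: float
    mr: float
    ehl: float
    tb: float | None
    ta: float
    mb: float | None = None
    bird_id: str | None = None
    group: str | None = None
    acclimation: str = "initial"
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.vo2 < 0:
            raise ValueError("vo2 must be non-negative")
        if self.ewl < 0:
            raise ValueError("ewl must be non-negative")
        if self.vo2 > 0 and not 0.6 <= self.rer <= 1.1:
            warnings.warn(
                f"RER {self.rer:.3f} outside the physiological range 0.6-1.1",
                stacklevel=2,
            )


def _rates_arrays(feo2, feco2, feh2o, flow, mode, fio2, fico2, fih2o):
    """Vectorised mass-balance inversion on plain arrays (wet/dry basis as above)."""
    inert_in = 1.0 - fio2 - fico2 - fih2o
    inert_out = 1.0 - feo2 - feco2
    if mode == "push_chamber":
        fri = flow
        fred = fri * inert_in / inert_out
    else:  # pull modes meter the dried excurrent stream
        fred = flow
        fri = fred * inert_out / inert_in
    vo2 = fri * fio2 - fred * feo2
    vco2 = fred * feco2 - fri * fico2
    fre = fred / (1.0 - feh2o)
    vh2o = fre * feh2o - fri * fih2o
    return vo2, vco2, vh2o * MG_H2O_PER_ML


def gas_exchange_rates(sample: GasSample, tolerance: float = 0.01) -> GasExchangeRates:
    """Invert the steady-state mass balance of one analyzer reading.

    Returns V̇O₂ and V̇CO₂ in ml min⁻¹ and EWL in mg min⁻¹.  Small negative
    rates (|rate| < `tolerance` ml min⁻¹ or mg min⁻¹), which arise from
    analyzer noise around a true zero, are set to 0 with a warning; larger
    negative rates mark the record as flagged rather than being clamped.
    """
    vo2, vco2, ewl = _rates_arrays(
        sample.feo2,
        sample.feco2,
        sample.ph2o / sample.bp,
        sample.flow,
        sample.mode,
        sample.fio2,
        sample.fico2,
        sample.pih2o / sample.bp,
    )
    flagged = False
    out = []
    for name, v in (("vo2", vo2), ("vco2", vco2), ("ewl", ewl)):
        if -tolerance <= v < 0.0:
            warnings.warn(
                f"{name} = {v:.3g} slightly negative; set to 0 (analyzer noise)",
                stacklevel=2,
            )
            v = 0.0
        elif v < -tolerance:
            flagged = True
        out.append(v)
    return GasExchangeRates(out[0], out[1], out[2], flagged=flagged)


def respiratory_exchange_ratio(vo2: float, vco2: float) -> float:
    """RER = V̇CO₂/V̇O₂; requires positive oxygen consumption."""
    if vo2 <= 0:
        raise ValueError("RER undefined for vo2 <= 0")
    return vco2 / vo2


def metabolic_rate(vo2: float, rer: float) -> float:
    """Metabolic rate in W from V̇O₂ (ml min⁻¹) via the oxyjoule equivalent.

    MR = V̇O₂ · (16 + 5.164·RER) / 60, i.e. (16 + 5.164·RER) joules are
    released per ml O₂ consumed, divided by 60 s to give watts.
    """
    if vo2 < 0:
        raise ValueError("vo2 must be non-negative")
    if vo2 > 0 and not 0.6 <= rer <= 1.1:
        warnings.warn(
            f"RER {rer:.3f} outside the physiological range 0.6-1.1", stacklevel=2
        )
    return vo2 * (16.0 + 5.164 * rer) / 60.0


def ehl_from_ewl(ewl: float) -> float:
    """Evaporative heat loss (W) from water loss (mg min⁻¹) at 2.4 J mg⁻¹."""
    if np.any(np.asarray(ewl) < 0):
        raise ValueError("ewl must be non-negative")
    return ewl * LATENT_HEAT_J_PER_MG / 60.0


def surface_area(mb: float) -> float:
    """Body surface area A_s (cm²) from body mass (g): A_s = 10·m_b^0.667."""
    if np.any(np.asarray(mb) <= 0):
        raise ValueError("body mass must be positive")
    return 10.0 * mb**0.667


def thermal_conductance(mr: float, ehl: float, tb: float, ta: float, mb: float) -> float:
    """Dry thermal conductance C = (MR − EHL)/((T_b − T_a)·A_s), W °C⁻¹ cm⁻².

    Only meaningful below the lower critical temperature, where the animal
    is warmer than its surroundings; calling it with ``tb <= ta`` raises.
    Multiply by 1000 for the customary mW °C⁻¹ cm⁻² display scale.
    """
    if tb <= ta:
        raise ValueError(
            f"thermal conductance is defined for tb > ta; got tb={tb}, ta={ta}"
        )
    if mr < ehl:
        warnings.warn(
            "EHL exceeds MR; conductance will be negative (check the record)",
            stacklevel=2,
        )
    return (mr - ehl) / ((tb - ta) * surface_area(mb))
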