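"""Partitioning evaporative heat loss into respiratory and cutaneous avenues.

During a mask session the bird's head is enclosed in a mask flushed by its
own airline while the body sits in a chamber with a second, slower line:
water added to the mask line is respiratory (plus head-skin) evaporation,
water added to the chamber line is cutaneous evaporation.  Both lines are
pull-mode, flow metered after drying.  The mask line also carries the O₂
and CO₂ signals, so the restrained bird's metabolic rate comes with it.

Note the semantic caveat: the mask covers the whole head, so the
"respiratory" avenue includes evaporation from head skin and eye surfaces;
no correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .calorimetry import (
    GasSample,
    ehl_from_ewl,
    gas_exchange_rates,
    metabolic_rate,
    respiratory_exchange_ratio,
)

__all__ = ["PartitionRecord", "partition_ehl", "summarize_partition"]


@dataclass
class PartitionRecord:
    """Respiratory/cutaneous evaporative partition of one bird at one T_a."""

    bird_id: str | None
    ta_set: float | None  # categorical exposure temperature, °C (25 or 40)
    rewl: float  # mg min⁻¹
    cewl: float  # mg min⁻¹
    rehl: float  # W
    cehl: float  # W
    tehl: float  # W (= rehl + cehl)
    rehl_cehl_ratio: float
    cehl_fraction: float  # CEHL / TEHL
    mr: float | None = None  # W, from the mask line
    tb: float | None = None  # °C
    flagged: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def partition_ehl(
    mask_line: GasSample,
    chamber_line: GasSample,
    bird_id: str | None = None,
    ta_set: float | None = None,
    tb: float | None = None,
    tolerance: float = 0.01,
) -> PartitionRecord:
    """Compute REWL/CEWL (and REHL/CEHL in W) from the two-line readings.

    The mask line must be ``pull_mask`` and the chamber line
    ``pull_chamber``; the chamber line needs only its water signal.
    Negative water excess beyond ``tolerance`` flags the record.
    """
    if mask_line.mode != "pull_mask":
        raise ValueError("mask_line must be in pull_mask mode")
    if chamber_line.mode != "pull_chamber":
        raise ValueError("chamber_line must be in pull_chamber mode")
    mask = gas_exchange_rates(mask_line, tolerance=tolerance)
    chamber = gas_exchange_rates(chamber_line, tolerance=tolerance)
    rewl, cewl = mask.ewl, chamber.ewl
    flagged = mask.flagged or chamber.flagged
    rehl = ehl_from_ewl(max(rewl, 0.0))
    cehl = ehl_from_ewl(max(cewl, 0.0))
    tehl = rehl + cehl
    mr = None
    if mask.vo2 > 0:
        mr = metabolic_rate(mask.vo2, respiratory_exchange_ratio(mask.vo2, mask.vco2))
    return PartitionRecord(
        bird_id=bird_id,
        ta_set=ta_set,
        rewl=rewl,
        cewl=cewl,
        rehl=rehl,
        cehl=cehl,
        tehl=tehl,
        rehl_cehl_ratio=rehl / cehl if cehl > 0 else np.inf,
        cehl_fraction=cehl / tehl if tehl > 0 else np.nan,
        mr=mr,
        tb=tb,
        flagged=flagged,
    )


def summarize_partition(records, by: str = "ta_set") -> pd.DataFrame:
    """Per-stratum summary of the partition records.

    Means, medians and quartiles of each avenue and ratio per level of
    ``by`` (normally the exposure temperature).  Two aggregate cutaneous
    contributions are reported because they answer different questions:
    ``cehl_fraction_mean`` averages the per-bird fractions, while
    ``cehl_fraction_pooled`` is Σ CEHL / Σ TEHL over the stratum.
    Empty strata are omitted with a warning.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame([r.to_dict() for r in records])
    if records.empty:
        warnings.warn("no partition records to summarize", stacklevel=2)
        return pd.DataFrame()
    rows = []
    for level, sub in records.groupby(by):
        sub = sub.dropna(subset=["rehl", "cehl"])
        if sub.empty:
            warnings.warn(f"stratum {by}={level!r} is empty; omitted", stacklevel=2)
            continue
        row = {by: level, "n": len(sub)}
        for col in ("rehl", "cehl", "tehl", "rehl_cehl_ratio", "cehl_fraction"):
            v = sub[col].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            row[f"{col}_mean"] = float(np.mean(v))
            row[f"{col}_median"] = float(np.median(v))
            row[f"{col}_q25"] = float(np.percentile(v, 25))
            row[f"{col}_q75"] = float(np.percentile(v, 75))
        row["cehl_fraction_pooled"] = float(sub["cehl"].sum() / sub["tehl"].sum())
        rows.append(row)
    return pd.DataFrame(rows)
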