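"""Raw multiplexed trace processing: demultiplex, baseline-correct, select.

A multiplexed flow-through system cycles the gas analyzers across several
animal chambers and, at least every 20 minutes, a reference airline that
reads the incurrent composition.  Processing a run means

1. :func:`demultiplex` — split the trace into per-animal dwell segments,
   discard the washout transient after every valve switch, and attach the
   bracketing reference readings to each segment;
2. :func:`baseline_correct` — interpolate the incurrent composition
   linearly in time between the bracketing references (removing affine
   analyzer drift exactly) and invert the mass balance sample by sample;
3. :func:`select_steady_state` — pick the window that defines the
   steady-state observation: the 2-min window with the lowest mean V̇O₂,
   or the most stable (lowest-variance) 5-min window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calorimetry import _rates_arrays, STANDARD_BP_KPA

__all__ = [
    "RawTrace",
    "TraceSegment",
    "ReferenceReading",
    "SteadyStateSelection",
    "demultiplex",
    "baseline_correct",
    "select_steady_state",
    "process_trace",
]

REFERENCE_CHANNEL = "REF"

TRACE_COLUMNS = ("time_s", "channel", "feo2", "feco2", "ph2o_kpa", "flow_mlmin", "ta_c")


@dataclass
class RawTrace:
    """A validated raw multiplexed trace (uniform sampling, e.g. 0.5 Hz)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRACE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"raw trace lacks columns: {missing}")
        t = self.data["time_s"].to_numpy(dtype=float)
        if not np.all(np.diff(t) > 0):
            raise ValueError("time_s must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.data["time_s"].to_numpy(dtype=float))))


@dataclass
class ReferenceReading:
    """Mean incurrent composition of one reference dwell."""

    time_mid: float
    fio2: float
    fico2: float
    pih2o: float


@dataclass
class TraceSegment:
    """One animal dwell with its washout removed and references attached."""

    bird_id: str
    channel: object
    data: pd.DataFrame  # post-washout samples
    ref_before: ReferenceReading | None
    ref_after: ReferenceReading | None
    flags: list = field(default_factory=list)


@dataclass
class SteadyStateSelection:
    """The selected steady-state window and its averages."""

    window_start: float
    window_end: float
    criterion: str
    mean_vo2: float
    mean_ewl: float
    mean_tb: float | None = None
    mean_vco2: float | None = None
    mean_ta: float | None = None


def _runs(channel: pd.Series):
    """Contiguous runs of the channel column as (value, start_idx, end_idx)."""
    vals = channel.to_numpy()
    change = np.flatnonzero(vals[1:] != vals[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(vals)]))
    return [(vals[s], s, e) for s, e in zip(starts, ends)]


def _summarize_reference(df: pd.DataFrame, tail_s: float = 180.0) -> ReferenceReading:
    """Mean of the last ``tail_s`` seconds of a reference dwell (its own
    washout discarded implicitly by using only the tail)."""
    t = df["time_s"].to_numpy(dtype=float)
    tail = df[t >= t[-1] - tail_s + 1e-9]
    return ReferenceReading(
        time_mid=float(tail["time_s"].mean()),
        fio2=float(tail["feo2"].mean()),
        fico2=float(tail["feco2"].mean()),
        pih2o=float(tail["ph2o_kpa"].mean()),
    )


def demultiplex(
    trace: RawTrace | pd.DataFrame,
    mux_map: dict,
    washout_discard: float = 60.0,
) -> dict[str, list[TraceSegment]]:
    """Split a multiplexed trace into per-bird segment lists.

    ``mux_map`` maps channel ids to bird ids; the channel ``REF`` marks
    reference air and needs no mapping.  The first ``washout_discard``
    seconds after every valve switch are dropped.  Every animal segment is
    annotated with the nearest preceding and following reference readings;
    a segment missing one of them is flagged (``incomplete_reference``).
    """
    if isinstance(trace, pd.DataFrame):
        trace = RawTrace(trace)
    df = trace.data.reset_index(drop=True)
    runs = _runs(df["channel"].astype(str))
    known = {str(k) for k in mux_map} | {REFERENCE_CHANNEL}
    for ch, _, _ in runs:
        if ch not in known:
            raise ValueError(f"channel {ch!r} not present in the multiplexer map")

    refs: list[tuple[int, ReferenceReading]] = []
    animal_runs = []
    for i, (ch, s, e) in enumerate(runs):
        sub = df.iloc[s:e]
        if ch == REFERENCE_CHANNEL:
            refs.append((i, _summarize_reference(sub)))
        else:
            animal_runs.append((i, ch, sub))

    if len(refs) < 2:
        warnings.warn(
            "fewer than two reference dwells in the run; drift correction "
            "will degenerate to a constant baseline",
            stacklevel=2,
        )

    out: dict[str, list[TraceSegment]] = {str(v): [] for v in mux_map.values()}
    str_map = {str(k): v for k, v in mux_map.items()}
    for i, ch, sub in animal_runs:
        t0 = float(sub["time_s"].iloc[0])
        kept = sub[sub["time_s"] >= t0 + washout_discard]
        before = [r for j, r in refs if j < i]
        after = [r for j, r in refs if j > i]
        seg = TraceSegment(
            bird_id=str(str_map[ch]),
            channel=ch,
            data=kept.reset_index(drop=True),
            ref_before=before[-1] if before else None,
            ref_after=after[0] if after else None,
        )
        if seg.ref_before is None or seg.ref_after is None:
            seg.flags.append("incomplete_reference")
        out[seg.bird_id].append(seg)
    return out


def baseline_correct(segment: TraceSegment, bp: float = STANDARD_BP_KPA) -> pd.DataFrame:
    """Compute drift-corrected rates for every sample of one segment.

    The incurrent composition at each sample time is the linear
    interpolation between the bracketing reference readings; when only one
    reference exists it is used as a constant with a warning.  Returns the
    segment data with ``vo2``, ``vco2`` and ``ewl`` columns appended.
    """
    rb, ra = segment.ref_before, segment.ref_after
    if rb is None and ra is None:
        raise ValueError("segment has no reference readings at all")
    if rb is None or ra is None:
        warnings.warn(
            "only one reference reading available; using it as a constant "
            "baseline (no drift correction)",
            stacklevel=2,
        )
        rb = ra = rb or ra
    df = segment.data.copy()
    t = df["time_s"].to_numpy(dtype=float)
    if ra.time_mid == rb.time_mid:
        w = np.zeros_like(t)
    else:
        w = (t - rb.time_mid) / (ra.time_mid - rb.time_mid)
    fio2 = rb.fio2 + w * (ra.fio2 - rb.fio2)
    fico2 = rb.fico2 + w * (ra.fico2 - rb.fico2)
    pih2o = rb.pih2o + w * (ra.pih2o - rb.pih2o)
    vo2, vco2, ewl = _rates_arrays(
        df["feo2"].to_numpy(dtype=float),
        df["feco2"].to_numpy(dtype=float),
        df["ph2o_kpa"].to_numpy(dtype=float) / bp,
        df["flow_mlmin"].to_numpy(dtype=float),
        "push_chamber",
        fio2,
        fico2,
        pih2o / bp,
    )
    df["vo2"], df["vco2"], df["ewl"] = vo2, vco2, ewl
    return df


def select_steady_state(
    data: pd.DataFrame,
    criterion: str = "lowest_mean",
    width_s: float = 120.0,
) -> SteadyStateSelection:
    """Pick the steady-state window from a rate time series.

    ``lowest_mean`` minimises the window mean of V̇O₂ (2-min default);
    ``most_stable`` minimises the within-window variance of V̇O₂ (use
    ``width_s=300`` for the 5-min convention).  The window slides one
    sample at a time; ties go to the earliest window.  Concurrent EWL
    (and T_b / V̇CO₂ / T_a when present) are averaged over the same window.
    """
    if criterion not in ("lowest_mean", "most_stable"):
        raise ValueError(f"unknown criterion {criterion!r}")
    t = data["time_s"].to_numpy(dtype=float)
    vo2 = data["vo2"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("series too short for any window")
    dt = float(np.median(np.diff(t)))
    w = int(round(width_s / dt))
    if w < 1 or w > t.size:
        raise ValueError(
            f"window of {width_s} s ({w} samples) does not fit a segment of "
            f"{t.size} samples"
        )
    roll = pd.Series(vo2).rolling(w)
    score = roll.mean() if criterion == "lowest_mean" else roll.var(ddof=1)
    score = score.to_numpy()[w - 1 :]
    start = int(np.argmin(score))  # first minimum wins ties
    sl = slice(start, start + w)

    def mean_of(col):
        if col not in data.columns:
            return None
        return float(data[col].to_numpy(dtype=float)[sl].mean())

    return SteadyStateSelection(
        window_start=float(t[start]),
        window_end=float(t[start + w - 1] + dt),
        criterion=criterion,
        mean_vo2=float(vo2[sl].mean()),
        mean_ewl=mean_of("ewl"),
        mean_tb=mean_of("tb"),
        mean_vco2=mean_of("vco2"),
        mean_ta=mean_of("ta_c"),
    )


def process_trace(
    trace,
    mux_map: dict,
    washout_discard: float = 60.0,
    criterion: str = "lowest_mean",
    width_s: float = 120.0,
    bp: float = STANDARD_BP_KPA,
) -> pd.DataFrame:
    """Full pipeline: demultiplex → baseline-correct → select, per dwell.

    Returns one row per animal dwell with the selected window's mean rates,
    ready to be aggregated into a steady-state table.
    """
    segments = demultiplex(trace, mux_map, washout_discard=washout_discard)
    rows = []
    for bird, segs in segments.items():
        for seg in segs:
            rates = baseline_correct(seg, bp=bp)
            try:
                sel = select_steady_state(rates, criterion=criterion, width_s=width_s)
            except ValueError:
                seg.flags.append("segment_too_short")
                continue
            rows.append(
                {
                    "bird_id": bird,
                    "channel": seg.channel,
                    "window_start_s": sel.window_start,
                    "window_end_s": sel.window_end,
                    "vo2_mlmin": sel.mean_vo2,
                    "vco2_mlmin": sel.mean_vco2,
                    "ewl_mgmin": sel.mean_ewl,
                    "ta_c": sel.mean_ta,
                    "flags": ";".join(seg.flags),
                }
            )
    return pd.DataFrame(rows)
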