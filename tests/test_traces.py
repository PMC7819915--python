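"""Demultiplexing, drift correction and steady-state window selection."""

import numpy as np
import pandas as pd
import pytest

from thermoresp import (
    RawTrace,
    baseline_correct,
    demultiplex,
    process_trace,
    select_steady_state,
)
from thermoresp.synthetic import TraceConfig, generate_raw_trace

RATES = {i: (0.4 + 0.1 * i, 0.35 + 0.08 * i, 1.0 + 0.3 * i) for i in range(1, 9)}
MUX = {i: f"bird{i:02d}" for i in range(1, 9)}


@pytest.fixture(scope="module")
def clean_trace():
    return generate_raw_trace(RATES, TraceConfig(seed=1))


class TestDemultiplex:
    def test_single_channel_gets_both_references(self):
        trace, _ = generate_raw_trace({1: (0.7, 0.6, 1.5)}, TraceConfig(seed=0, n_cycles=1))
        segs = demultiplex(trace, {1: "b1"})
        assert list(segs) == ["b1"]
        (seg,) = segs["b1"]
        assert seg.ref_before is not None and seg.ref_after is not None
        assert not seg.flags

    def test_segment_durations_account_for_washout(self, clean_trace):
        trace, _ = clean_trace
        cfg = TraceConfig()
        segs = demultiplex(trace, MUX, washout_discard=60.0)
        assert len(segs) == 8
        n_dwells = sum(len(v) for v in segs.values())
        assert n_dwells == 8 * 3  # 8 channels x 3 rotation cycles
        kept = sum(len(s.data) for v in segs.values() for s in v)
        per_dwell = int(cfg.dwell_s / cfg.dt_s) - int(60.0 / cfg.dt_s)
        assert kept == n_dwells * per_dwell

    def test_unknown_channel_rejected(self, clean_trace):
        trace, _ = clean_trace
        with pytest.raises(ValueError, match="channel"):
            demultiplex(trace, {1: "b1"})

    def test_nonmonotonic_time_rejected(self):
        df = pd.DataFrame(
            {
                "time_s": [0.0, 2.0, 1.0],
                "channel": ["REF"] * 3,
                "feo2": 0.2095,
                "feco2": 0.0,
                "ph2o_kpa": 0.0,
                "flow_mlmin": 500.0,
                "ta_c": 30.0,
            }
        )
        with pytest.raises(ValueError, match="increasing"):
            RawTrace(df)


class TestBaselineCorrection:
    def test_zero_drift_recovers_exact_rates(self, clean_trace):
        trace, truth = clean_trace
        segs = demultiplex(trace, MUX)
        for bird, seglist in segs.items():
            ch = seglist[0].channel
            vo2_true = truth[int(ch)][0]
            rates = baseline_correct(seglist[0])
            assert rates["vo2"].mean() == pytest.approx(vo2_true, abs=1e-9)

    def test_affine_drift_removed_unbiased(self):
        cfg = TraceConfig(seed=3, drift_o2_per_s=1e-4 / 3600.0)
        trace, truth = generate_raw_trace(RATES, cfg)
        out = process_trace(trace, MUX)
        for row in out.itertuples():
            vo2_true = truth[int(row.channel)][0]
            assert abs(row.vo2_mlmin - vo2_true) / vo2_true < 0.01

    def test_missing_trailing_reference_warns_and_extrapolates(self):
        trace, _ = generate_raw_trace({1: (0.7, 0.6, 1.5)}, TraceConfig(seed=0, n_cycles=1))
        # drop the final reference dwell
        df = trace[~((trace["channel"] == "REF") & (trace["time_s"] > 400))]
        segs = demultiplex(RawTrace(df.reset_index(drop=True)), {1: "b1"})
        (seg,) = segs["b1"]
        assert "incomplete_reference" in seg.flags
        with pytest.warns(UserWarning, match="one reference"):
            rates = baseline_correct(seg)
        assert rates["vo2"].mean() == pytest.approx(0.7, abs=1e-9)


class TestWindowSelection:
    def _df(self, vo2, dt=2.0):
        n = len(vo2)
        return pd.DataFrame(
            {"time_s": np.arange(n) * dt, "vo2": vo2, "ewl": np.ones(n)}
        )

    def test_monotone_decreasing_picks_final_window(self):
        df = self._df(np.linspace(2.0, 1.0, 200))
        sel = select_steady_state(df, "lowest_mean", width_s=120)
        assert sel.window_end == pytest.approx(df["time_s"].iloc[-1] + 2.0)

    def test_planted_minimum_matches_exhaustive_search(self, rng):
        vo2 = 1.0 + 0.1 * rng.standard_normal(300)
        vo2[120:180] -= 0.5  # planted 2-min plateau at 2 s sampling
        df = self._df(vo2)
        sel = select_steady_state(df, "lowest_mean", width_s=120)
        w = 60
        means = [vo2[i : i + w].mean() for i in range(300 - w + 1)]
        assert sel.window_start == pytest.approx(2.0 * int(np.argmin(means)))
        assert sel.mean_vo2 == pytest.approx(min(means))

    def test_most_stable_matches_exhaustive_variance_search(self, rng):
        vo2 = np.sin(np.arange(400) / 15.0) + 0.05 * rng.standard_normal(400)
        vo2[200:350] = 1.0 + 0.001 * rng.standard_normal(150)
        df = self._df(vo2)
        sel = select_steady_state(df, "most_stable", width_s=300)
        w = 150
        variances = [vo2[i : i + w].var(ddof=1) for i in range(400 - w + 1)]
        assert sel.window_start == pytest.approx(2.0 * int(np.argmin(variances)))

    def test_constant_series_tie_breaks_to_first_window(self):
        df = self._df(np.ones(200))
        sel = select_steady_state(df, "most_stable", width_s=120)
        assert sel.window_start == 0.0

    def test_window_wider_than_segment_rejected(self):
        df = self._df(np.ones(10))
        with pytest.raises(ValueError, match="does not fit"):
            select_steady_state(df, "lowest_mean", width_s=120)


class TestEndToEnd:
    def test_noisy_pipeline_recovers_truth_within_two_sd(self):
        cfg = TraceConfig(seed=11, noise_o2=2e-6, noise_co2=1e-6, noise_ph2o=2e-4)
        trace, truth = generate_raw_trace(RATES, cfg)
        out = process_trace(trace, MUX)
        # analyzer noise propagated through the mass balance, for the window mean
        w = 60
        sd_vo2 = 500.0 * 2e-6 / np.sqrt(w)
        ok = 0
        for row in out.itertuples():
            vo2_true = truth[int(row.channel)][0]
            ok += abs(row.vo2_mlmin - vo2_true) <= 4 * sd_vo2
        assert ok / len(out) >= 0.95
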