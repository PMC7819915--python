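"""Segmented regression: exact recovery, grid-oracle equivalence, selection."""

import numpy as np
import pytest

from thermoresp import SegmentedRegression, select_model_type


def oracle_sse_1bp(x, y, b, constraints=("free", "free")):
    """Independent SSE at a fixed breakpoint: direct hinge-basis least squares."""
    cols = [np.ones_like(x)]
    if constraints[0] == "free":
        cols.append(x)
        if constraints[1] == "free":
            cols.append(np.maximum(x - b, 0.0))
    else:
        # flat-then-rise: y = a + s*(x-b)+
        if constraints[1] == "free":
            cols.append(np.maximum(x - b, 0.0))
    X = np.column_stack(cols)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


class TestExactRecovery:
    def test_noiseless_flat_then_rise(self):
        x = np.arange(0.0, 11.0)
        y = np.where(x < 5, 1.0, 1.0 + 0.5 * (x - 5))
        res = SegmentedRegression(y, x, 1, ("horizontal", "free")).fit()
        assert res.breakpoints[0] == pytest.approx(5.0, abs=1e-6)
        assert res.slopes == pytest.approx([0.0, 0.5], abs=1e-9)
        assert res.sse == pytest.approx(0.0, abs=1e-18)
        assert res.r2 == pytest.approx(1.0)

    def test_noiseless_three_segment_profile(self):
        x = np.arange(22.0, 44.5, 0.25)
        b1, b2 = 34.87, 37.47
        y = 0.24 + 0.015 * np.clip(b1 - x, 0, None) + 0.013 * np.clip(x - b2, 0, None)
        res = SegmentedRegression(y, x, 2, ("free", "horizontal", "free")).fit()
        assert res.breakpoints == pytest.approx([b1, b2], abs=0.01)
        assert res.slopes == pytest.approx([-0.015, 0.0, 0.013], abs=1e-4)
        assert res.plateau_level() == pytest.approx(0.24, abs=1e-4)

    def test_continuity_at_breakpoints(self):
        rng = np.random.default_rng(5)
        x = np.sort(rng.uniform(0, 10, 60))
        y = np.where(x < 6, 2 + 0.3 * x, 2 + 1.8 + 0.9 * (x - 6)) + rng.normal(0, 0.2, 60)
        res = SegmentedRegression(y, x, 1).fit()
        b = res.breakpoints[0]
        left = res.slopes[0] * b + res.intercepts[0]
        right = res.slopes[1] * b + res.intercepts[1]
        assert left == pytest.approx(right, abs=1e-10)

    def test_horizontal_constraint_is_exact_zero(self):
        rng = np.random.default_rng(6)
        x = np.linspace(0, 10, 50)
        y = np.where(x < 5, 1.0, 1 + 0.4 * (x - 5)) + rng.normal(0, 0.05, 50)
        res = SegmentedRegression(y, x, 1, ("horizontal", "free")).fit()
        assert res.slopes[0] == 0.0


class TestGridOracle:
    @pytest.mark.parametrize("seed", range(10))
    def test_sse_not_worse_than_fine_grid(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        x = np.sort(rng.uniform(0, 10, n))
        b_true = rng.uniform(3, 7)
        y = 1 + 0.2 * x + rng.uniform(0.3, 1.0) * np.maximum(x - b_true, 0)
        y += rng.normal(0, 0.3, n)
        fit = SegmentedRegression(y, x, 1).fit()
        grid = np.arange(x[2], x[-3], 0.01)
        oracle = min(oracle_sse_1bp(x, y, b) for b in grid)
        assert fit.sse <= oracle * (1 + 1e-8)

    def test_constrained_fit_matches_constrained_oracle(self):
        rng = np.random.default_rng(42)
        x = np.sort(rng.uniform(0, 10, 80))
        y = 2.0 + 0.5 * np.maximum(x - 4.3, 0) + rng.normal(0, 0.15, 80)
        fit = SegmentedRegression(y, x, 1, ("horizontal", "free")).fit()
        grid = np.arange(x[2], x[-3], 0.01)
        oracle = min(
            oracle_sse_1bp(x, y, b, ("horizontal", "free")) for b in grid
        )
        assert fit.sse <= oracle * (1 + 1e-8)


class TestValidationAndBootstrap:
    def test_too_few_points_per_segment_rejected(self):
        with pytest.raises(ValueError, match="per prospective segment"):
            SegmentedRegression([1, 2, 3, 4], [1, 2, 3, 4], 1)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="all equal"):
            SegmentedRegression(np.arange(10.0), np.ones(10), 0)

    def test_cluster_bootstrap_gives_finite_se(self):
        rng = np.random.default_rng(3)
        birds = np.repeat(np.arange(12), 8)
        x = np.tile(np.linspace(0, 10, 8), 12)
        u = rng.normal(0, 0.3, 12)
        y = 1 + 0.5 * np.maximum(x - 5, 0) + u[birds] + rng.normal(0, 0.2, x.size)
        res = SegmentedRegression(y, x, 1, ("horizontal", "free"), groups=birds).fit(
            bootstrap=60, seed=9
        )
        assert res.breakpoint_se is not None
        assert 0 < res.breakpoint_se[0] < 3.0
        assert res.n_boot > 50

    def test_bootstrap_se_shrinks_with_more_birds(self):
        """Roughly 1/sqrt(n): quadrupling birds shrinks the breakpoint SE."""

        def se_for(n_birds, seed):
            rng = np.random.default_rng(seed)
            birds = np.repeat(np.arange(n_birds), 8)
            x = np.tile(np.linspace(0, 10, 8), n_birds)
            y = (
                1
                + 0.5 * np.maximum(x - 5, 0)
                + rng.normal(0, 0.3, n_birds)[birds]
                + rng.normal(0, 0.3, x.size)
            )
            return SegmentedRegression(
                y, x, 1, ("horizontal", "free"), groups=birds
            ).fit(bootstrap=80, seed=seed)

        ratios = []
        for seed in (0, 1, 2):
            small = se_for(18, seed).breakpoint_se[0]
            large = se_for(72, seed).breakpoint_se[0]
            ratios.append(small / large)
        assert 1.2 <= np.median(ratios) <= 2.9


class TestModelSelection:
    def test_pure_linear_selects_zero_breakpoints(self):
        rng = np.random.default_rng(11)
        x = np.linspace(0, 10, 80)
        y = 1 + 0.4 * x + rng.normal(0, 0.2, 80)
        best = select_model_type(x, y, [(0, None), (1, None)])
        assert best.n_breakpoints == 0

    def test_clear_breakpoint_selected(self):
        rng = np.random.default_rng(12)
        x = np.linspace(0, 10, 100)
        signal = 1 + 0.0 * x + 1.0 * np.maximum(x - 5, 0)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = signal + rng.normal(0, 0.1 * np.ptp(signal), 100)
            best = select_model_type(x, y, [(0, None), (1, None)])
            hits += best.n_breakpoints == 1
        assert hits >= 19  # >= 95 % of replicates

    def test_plateau_then_rise_marks_first_segment_horizontal(self):
        rng = np.random.default_rng(13)
        x = np.linspace(0, 10, 100)
        y = 2 + 0.8 * np.maximum(x - 5, 0) + rng.normal(0, 0.1, 100)
        best = select_model_type(
            x, y, [(0, None), (1, ("horizontal", "free")), (1, None)]
        )
        assert best.n_breakpoints == 1
        assert best.constraints[0] == "horizontal"

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_model_type(np.arange(10.0), np.arange(10.0), [])
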