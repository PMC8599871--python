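"""Segmentation, slope-vs-force assembly and inversion-force estimation."""

import numpy as np
import pytest

from bldna.phase_transition import bl_slope, default_config, inversion_force
from bldna.plectoneme import PlectonemeParams
from bldna.synthetic import NoiseModel, TwistTrace, gen_twist_trace
from bldna.trace_analysis import (
    NoSlopeCrossingError,
    SegmentationError,
    SlopeEstimate,
    estimate_f_star,
    segment_trace,
    slope_vs_force,
)


def family(config, forces, reps=1, sd=0.0, seed0=0, plect=PlectonemeParams()):
    traces = []
    k = 0
    for f in forces:
        for r in range(reps):
            traces.append(
                gen_twist_trace(
                    float(f),
                    (-900, 100),
                    config,
                    plect,
                    NoiseModel(sd, seed0 + k),
                    trace_id=f"F{f:g}-r{r}",
                )
            )
            k += 1
    return traces


class TestSegmentTrace:
    def test_noise_free_breakpoints_near_truth(self, wt_config, plect):
        # +60 turns keeps the B plectonemic branch clear of the zero-
        # extension clip at 2.3 pN, so all three regimes are linear
        trace = gen_twist_trace(
            2.3, (-900, 60), wt_config, plect, NoiseModel(0.0, 0), step=1
        )
        seg = segment_trace(trace)
        assert seg.breakpoints[0] == pytest.approx(wt_config.n_t_max, abs=2)
        assert seg.breakpoints[1] == pytest.approx(wt_config.n_b_max, abs=2)
        assert not seg.single_regime_suspected

    def test_noisy_bl_slope_within_two_stderr(self, wt_config, plect):
        truth = bl_slope(2.3, wt_config)
        hits = 0
        for seed in range(5):
            trace = gen_twist_trace(
                2.3, (-900, 100), wt_config, plect, NoiseModel(10.0, seed)
            )
            est = segment_trace(trace).slopes["BL"]
            if abs(est.slope - truth) <= 2 * est.stderr:
                hits += 1
        assert hits >= 4

    def test_pure_linear_trace_flagged(self):
        n_t = np.arange(-300, 301, 5)
        trace = TwistTrace(
            trace_id="lin",
            force=2.0,
            n_t=n_t,
            extension=2000.0 + 0.5 * n_t.astype(float) + 400.0,
        )
        seg = segment_trace(trace)
        assert seg.single_regime_suspected
        for est in seg.slopes.values():
            assert est.slope == pytest.approx(0.5, abs=1e-9)

    def test_too_few_points_rejected(self, wt_config):
        trace = TwistTrace(
            trace_id="short",
            force=2.0,
            n_t=np.arange(0, 11),
            extension=np.linspace(100.0, 200.0, 11),
        )
        with pytest.raises(SegmentationError):
            segment_trace(trace)

    def test_exhaustive_beats_random_candidates(self, wt_config, plect):
        # the global SSE minimiser can never lose to any sampled candidate
        trace = gen_twist_trace(
            2.3, (-900, 100), wt_config, plect, NoiseModel(10.0, 1)
        )
        seg = segment_trace(trace)
        x = trace.n_t.astype(float)
        y = trace.extension
        rng = np.random.default_rng(0)
        n = x.size
        for _ in range(50):
            b1 = rng.integers(4, n - 8)
            b2 = rng.integers(b1 + 4, n - 3)
            sse = 0.0
            for lo, hi in ((0, b1), (b1, b2), (b2, n)):
                coef = np.polyfit(x[lo:hi], y[lo:hi], 1)
                sse += float(
                    np.sum((y[lo:hi] - np.polyval(coef, x[lo:hi])) ** 2)
                )
            assert seg.sse <= sse + 1e-6


class TestSlopeVsForce:
    def test_noise_free_slopes_match_model(self, wt_config, plect):
        forces = [1.5, 2.5, 3.5]
        traces = family(wt_config, forces)
        ests = slope_vs_force(traces, "BL", window=(-700, -100))
        assert len(ests) == 3
        for est in ests:
            assert est.slope == pytest.approx(
                bl_slope(est.force, wt_config), rel=1e-8, abs=1e-12
            )

    def test_bl_slopes_decrease_through_zero(self, wt_config, plect):
        traces = family(wt_config, np.linspace(1.0, 4.0, 9))
        ests = slope_vs_force(traces, "BL", window=(-700, -100))
        slopes = [e.slope for e in ests]
        assert np.all(np.diff(slopes) < 0)
        assert slopes[0] > 0 > slopes[-1]

    def test_b_regime_reported_absolute(self, wt_config, plect):
        traces = family(wt_config, [2.3])
        ests = slope_vs_force(traces, "B", window=(10, 100))
        assert ests[0].slope > 0  # raw plectonemic slope is negative

    def test_absent_regime_skipped_with_warning(self, wt_config, plect, caplog):
        traces = family(wt_config, [2.3])
        # window outside the trace: regime absent everywhere
        ests = slope_vs_force(traces, "BL", window=(2000, 3000))
        assert ests == []
        assert any("skipped" in r.message for r in caplog.records)


class TestEstimateFStar:
    def test_wt_family_recovers_inversion_force(self, wt_config, plect):
        forces = np.arange(1.0, 4.01, 0.25)
        traces = family(wt_config, forces)
        ests = slope_vs_force(traces, "BL", window=(-700, -100))
        est = estimate_f_star(ests)
        truth = inversion_force(wt_config).f_star
        assert est.f_star == pytest.approx(truth, abs=0.25)

    def test_dap_family_recovers_inversion_force(self, dap_config, plect):
        forces = np.arange(1.0, 4.01, 0.25)
        traces = family(dap_config, forces)
        ests = slope_vs_force(traces, "BL", window=(-700, -100))
        est = estimate_f_star(ests)
        truth = inversion_force(dap_config).f_star
        assert est.f_star == pytest.approx(truth, abs=0.25)

    def test_no_sign_change_raises(self):
        ests = [
            SlopeEstimate("BL", 0.5, 0.01, 1.0, 10, (-700, -100)),
            SlopeEstimate("BL", 0.3, 0.01, 2.0, 10, (-700, -100)),
        ]
        with pytest.raises(NoSlopeCrossingError):
            estimate_f_star(ests)

    def test_bootstrap_ci_brackets_estimate(self, wt_config, plect):
        forces = np.linspace(1.0, 4.0, 9)
        traces = family(wt_config, forces, reps=3, sd=10.0)
        ests, per_trace = slope_vs_force(
            traces, "BL", window=(-700, -100), return_per_trace=True
        )
        est = estimate_f_star(ests, per_trace=per_trace, n_boot=199, seed=1)
        assert est.ci_low <= est.f_star <= est.ci_high
        assert est.ci_high - est.ci_low < 1.0
        assert "bootstrap" in est.method
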