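"""Linear calibration fits, conversion, slope-bias test, detection power."""

import numpy as np
import pytest

from cici_cal.calibration import (
    CalibrationPoint,
    average_intra_slope,
    background_subtract,
    detection_limit,
    fit_linear,
    signal_to_frequency,
    slope_bias_test,
)


def _points(pair_id, f, s, s0=None):
    return [
        CalibrationPoint(pair_id, i, fi, si, s0 if s0 is None else s0[i])
        for i, (fi, si) in enumerate(zip(f, s))
    ]


class TestFitLinear:
    def test_exact_line_recovered(self):
        f = [0.0, 0.2, 0.5, 0.8]
        fit = fit_linear(_points("p", f, [2 * x + 0.1 for x in f]))
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.1)
        assert fit.r_squared == pytest.approx(1.0)

    def test_two_points_interpolate_exactly(self):
        fit = fit_linear(_points("p", [0.1, 0.9], [1.0, 5.0]))
        assert fit.slope == pytest.approx(5.0)
        assert fit.intercept == pytest.approx(0.5)

    def test_noisy_recovery_within_fitted_se(self):
        # slope 3 recovered within 3 fitted SEs in >=95/100 seeded repeats
        hits = 0
        f = np.tile([0.0, 0.25, 0.5, 0.75, 1.0], 2)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            s = 3.0 * f + rng.normal(0, 0.05, size=f.size)
            fit = fit_linear(_points("p", f, s))
            hits += abs(fit.slope - 3.0) < 3 * fit.slope_se
        assert hits >= 95

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            fit_linear(_points("p", [0.5, 0.5], [1.0, 2.0]))
        with pytest.raises(ValueError):
            fit_linear(_points("p", [0.5], [1.0]))


class TestBackgroundSubtract:
    def test_zero_after_subtracting_self(self):
        pts = _points("p", [0.1], [0.7], s0=[0.7])
        assert background_subtract(pts)[0].signal == 0.0

    def test_constant_background_leaves_slope(self):
        f = [0.0, 0.3, 0.6, 0.9]
        s = [2 * x + 0.5 for x in f]
        pts = [CalibrationPoint("p", i, fi, si, 0.5) for i, (fi, si) in enumerate(zip(f, s))]
        assert fit_linear(background_subtract(pts)).slope == pytest.approx(
            fit_linear(pts).slope
        )

    def test_missing_background_rejected(self):
        with pytest.raises(ValueError):
            background_subtract(_points("p", [0.1], [0.7]))


class TestSlopeAveragingAndConversion:
    def test_average_intra_slope(self):
        fits = [
            fit_linear(_points(pid, [0.0, 1.0], [0.0, m]))
            for pid, m in (("a", 2.0), ("b", 3.0), ("c", 4.0), ("x", 99.0))
        ]
        assert average_intra_slope(fits, ["a", "b", "c"]) == pytest.approx(3.0)
        assert average_intra_slope(fits, ["c", "b", "a"]) == pytest.approx(3.0)
        with pytest.raises(ValueError):
            average_intra_slope(fits, ["nope"])

    def test_conversion_endpoints_and_clipping(self):
        assert signal_to_frequency(3.0, 3.0) == 1.0
        assert signal_to_frequency(0.0, 3.0) == 0.0
        assert signal_to_frequency(9.0, 3.0) == 1.0  # clipped
        assert signal_to_frequency(1.5, 3.0, intercept=0.5) == pytest.approx(1.0 / 3)
        with pytest.raises(ValueError):
            signal_to_frequency(1.0, 0.0)

    def test_round_trip_on_simulated_junctions(self, bins, model, intra_pair):
        # calibrate on a titration grid, then convert junction signals from
        # independent libraries back into contact frequencies
        from cici_cal.hicops import junction_signal, kr_balance, normalize_to_smallest, restriction_site_correction
        from cici_cal.hicsim import JunctionSpec, simulate_hic

        # calibration frequencies follow the titration design (ratios of a
        # 0.65 induced population into a 0.02 background), as in the study
        fit_grid = [0.02 + r * 0.63 for r in (0.0, 0.25, 0.5, 0.75, 1.0)]
        eval_grid = [0.05, 0.2, 0.5]
        mats = [
            simulate_hic(bins, [JunctionSpec(intra_pair, p)], model, 18_000_000, 0.2, seed=100 + i)
            for i, p in enumerate(fit_grid + eval_grid)
        ]
        processed = []
        for m in normalize_to_smallest(mats):
            m = restriction_site_correction(m)
            kr_balance(m)
            processed.append(m)
        signals = [junction_signal(m, intra_pair, use_weights=True) for m in processed]
        fit = fit_linear(_points("p", fit_grid, signals[: len(fit_grid)]))
        recovered = [
            float(signal_to_frequency(s, fit.slope, intercept=fit.intercept))
            for s in signals[len(fit_grid) :]
        ]
        assert np.allclose(recovered, eval_grid, atol=0.03)


class TestSlopeBiasTest:
    def test_identical_slopes_give_unit_ratio(self):
        fits = [
            fit_linear(_points(pid, [0.0, 1.0], [0.0, 2.0])) for pid in ("i1", "i2", "x1")
        ]
        ratio, ci = slope_bias_test(fits, ["i1", "i2"], ["x1"])
        assert ratio == pytest.approx(1.0)
        assert ci is None

    def test_hand_computed_ratio(self):
        fits = [
            fit_linear(_points(pid, [0.0, 1.0], [0.0, m]))
            for pid, m in (("i1", 2.0), ("i2", 2.0), ("i3", 2.0), ("x1", 3.0))
        ]
        ratio, _ = slope_bias_test(fits, ["i1", "i2", "i3"], ["x1"])
        assert ratio == pytest.approx(1.5)

    def test_bootstrap_ci_covers_unit_ratio_on_unbiased_points(self):
        rng = np.random.default_rng(11)
        points_by_pair = {}
        f = np.tile([0.0, 0.25, 0.5, 0.75, 1.0], 2)
        for pid in ("i1", "i2", "x1"):
            s = 2.0 * f + rng.normal(0, 0.05, size=f.size)
            points_by_pair[pid] = _points(pid, f, s)
        fits = [fit_linear(p) for p in points_by_pair.values()]
        ratio, ci = slope_bias_test(
            fits, ["i1", "i2"], ["x1"], points_by_pair, n_boot=500, seed=12
        )
        assert ci[0] <= 1.0 <= ci[1]

    def test_empty_class_rejected(self):
        fits = [fit_linear(_points("i1", [0.0, 1.0], [0.0, 2.0]))]
        with pytest.raises(ValueError):
            slope_bias_test(fits, ["i1"], ["missing"])


class TestDetectionLimit:
    def test_strong_loop_detected_and_monotone_in_depth(self, bins, model, intra_pair):
        limit_deep, report_deep = detection_limit(
            bins, intra_pair, model, [0.7], n_contacts=18_000_000, n_reps=3, seed=13
        )
        assert limit_deep == 0.7
        assert report_deep[0.7] == 3
        limit_shallow, _ = detection_limit(
            bins, intra_pair, model, [0.7], n_contacts=2_000_000, n_reps=3, seed=13
        )
        # a detectable p at low depth stays detectable at high depth
        assert limit_shallow is None or limit_deep <= limit_shallow

    def test_unsorted_grid_rejected(self, bins, model, intra_pair):
        with pytest.raises(ValueError):
            detection_limit(bins, intra_pair, model, [0.2, 0.1], n_reps=2)
        with pytest.raises(ValueError):
            detection_limit(bins, intra_pair, model, [0.1], n_reps=1)
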