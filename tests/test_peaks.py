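"""Baselines, integrals, double-peak detection, and leg handling."""

import numpy as np
import pytest

from halofit.errors import DataError, NotADoublePeakError, ParameterError
from halofit.image import Chromatogram
from halofit.peaks import (
    Baseline,
    PeakWindow,
    define_legs_manual,
    detect_double_peak,
    integrate_modelled_peak,
    integrate_peak,
    make_baseline,
    trim_legs,
)
from halofit.validation import MaskSpec, simulate_masking


def _chrom(y, x=None):
    y = np.asarray(y, float)
    x = np.arange(len(y), dtype=float) if x is None else np.asarray(x, float)
    return Chromatogram(positions=x, intensities=y)


class TestBaseline:
    def test_flat_chromatogram_gives_horizontal_baseline(self):
        chrom = _chrom(np.full(20, 40.0))
        base = make_baseline(chrom, PeakWindow(2, 17))
        x = np.linspace(2, 17, 7)
        np.testing.assert_allclose(base(x), 40.0)

    def test_trapezoid_base_integral(self):
        y = np.zeros(11)
        y[0], y[-1] = 10.0, 30.0
        chrom = _chrom(y)
        window = PeakWindow(0, 10)
        base = make_baseline(chrom, window)
        res = integrate_peak(chrom, window, base)
        assert res.base_integral == pytest.approx(20.0 * 10)

    def test_symmetric_shoulders_give_zero_slope(self):
        x = np.arange(21, dtype=float)
        y = 5 + 50 * np.exp(-((x - 10) ** 2) / 9.0)
        base = make_baseline(_chrom(y), PeakWindow(0, 20))
        assert base.left_anchor[1] == pytest.approx(base.right_anchor[1])


class TestIntegratePeak:
    def test_chromatogram_equal_to_baseline_nets_zero(self):
        y = np.linspace(3, 9, 15)
        chrom = _chrom(y)
        window = PeakWindow(0, 14)
        res = integrate_peak(chrom, window)
        assert res.net_integral == pytest.approx(0.0, abs=1e-12)

    def test_unit_rectangle_raw_integral(self):
        chrom = _chrom(np.ones(11))
        res = integrate_peak(chrom, PeakWindow(0, 10), Baseline((0, 0), (10, 0)))
        assert res.raw_integral == pytest.approx(10.0)

    def test_sampled_gaussian_matches_analytic_area(self):
        # the sigma^2-denominator Gaussian A*exp(-(x-mu)^2/sigma^2) has area
        # A*sigma*sqrt(pi)
        A, sigma = 100.0, 20.0
        x = np.arange(0, 1201, dtype=float)
        y = A * np.exp(-((x - 600) ** 2) / sigma**2)
        res = integrate_peak(_chrom(y), PeakWindow(0, 1200), Baseline((0, 0), (1200, 0)))
        assert res.raw_integral == pytest.approx(A * sigma * np.sqrt(np.pi), rel=1e-6)

    def test_net_integral_invariant_under_constant_shift(self):
        rng = np.random.default_rng(2)
        y = rng.uniform(10, 50, 31)
        chrom = _chrom(y)
        shifted = _chrom(y + 17.0)
        w = PeakWindow(0, 30)
        assert integrate_peak(chrom, w).net_integral == pytest.approx(
            integrate_peak(shifted, w).net_integral
        )


class TestIntegrateModelledPeak:
    def test_model_above_baseline_equals_plain_integration(self):
        x = np.arange(21, dtype=float)
        model = 10 + 50 * np.exp(-((x - 10) ** 2) / 9.0)
        base = Baseline((0, 5.0), (20, 5.0))
        res = integrate_modelled_peak(x, model, base)
        assert not res.intersection_limited
        assert res.base_integral == pytest.approx(5.0 * 20)

    def test_triangle_crossing_restricts_base_to_crossing_span(self):
        x = np.arange(0, 21, dtype=float)
        model = np.maximum(0.0, 10.0 - np.abs(x - 10))  # triangle, zero outside [0, 20]
        base = Baseline((0, 2.0), (20, 2.0))  # crossings at x = 2 and x = 18
        res = integrate_modelled_peak(x, model, base)
        assert res.intersection_limited
        assert res.base_integral == pytest.approx(2.0 * (18 - 2))

    def test_tangent_touch_uses_full_window(self):
        x = np.arange(0, 21, dtype=float)
        model = np.maximum(0.0, 10.0 - np.abs(x - 10))
        base = Baseline((0, 0.0), (20, 0.0))  # touches at the edges only
        res = integrate_modelled_peak(x, model, base)
        assert not res.intersection_limited

    def test_model_below_baseline_warns_and_nets_zero_by_status(self):
        x = np.arange(11, dtype=float)
        res = integrate_modelled_peak(x, np.full(11, 1.0), Baseline((0, 5.0), (10, 5.0)))
        assert res.status == "below-baseline"

    def test_restricted_base_never_exceeds_full_window_base(self):
        rng = np.random.default_rng(8)
        x = np.arange(51, dtype=float)
        for _ in range(20):
            model = rng.uniform(0, 10, 51)
            base = Baseline((0, rng.uniform(0, 5)), (50, rng.uniform(0, 5)))
            res = integrate_modelled_peak(x, model, base)
            full = float(np.trapezoid(base(x), x))
            assert res.base_integral <= full + 1e-9


class TestDetectDoublePeak:
    def test_masked_fixture_maxima_near_ground_truth(self, ideal_peaks):
        for chrom, truth in ideal_peaks[:6]:
            idx = truth.window.indices(chrom)
            x, y = chrom.positions[idx], chrom.intensities[idx]
            masked = simulate_masking(x, y, MaskSpec.from_window(x, y))
            dp = detect_double_peak(_chrom(masked, x), truth.window)
            n = len(x)
            lb = int(round(n / 6.0))
            # maxima should sit at the last unaffected samples next to the
            # masked region's boundaries
            assert abs(dp.left_max[0] - x[lb - 1]) <= 2
            assert abs(dp.right_max[0] - x[n - lb]) <= 2

    def test_unimodal_peak_raises_not_a_double_peak(self):
        x = np.arange(101, dtype=float)
        y = 100 * np.exp(-((x - 50) ** 2) / 200.0)
        with pytest.raises(NotADoublePeakError):
            detect_double_peak(_chrom(y), PeakWindow(0, 100))

    def test_three_maxima_keep_two_highest(self):
        x = np.arange(121, dtype=float)
        y = (
            60 * np.exp(-((x - 25) ** 2) / 50.0)
            + 50 * np.exp(-((x - 60) ** 2) / 50.0)
            + 70 * np.exp(-((x - 95) ** 2) / 50.0)
        )
        dp = detect_double_peak(_chrom(y), PeakWindow(0, 120))
        assert dp.left_max[0] == pytest.approx(25, abs=2)
        assert dp.right_max[0] == pytest.approx(95, abs=2)

    def test_equal_height_tie_prefers_widest_separation(self):
        x = np.arange(161, dtype=float)
        bump = lambda c: 50 * np.exp(-((x - c) ** 2) / 20.0)
        y = bump(20) + bump(80) + bump(140)
        dp = detect_double_peak(_chrom(y), PeakWindow(0, 160))
        assert dp.left_max[0] == pytest.approx(20, abs=2)
        assert dp.right_max[0] == pytest.approx(140, abs=2)

    def test_valley_strictly_below_both_shoulders_on_all_fixtures(self, ideal_peaks):
        for chrom, truth in ideal_peaks:
            idx = truth.window.indices(chrom)
            x, y = chrom.positions[idx], chrom.intensities[idx]
            masked = simulate_masking(x, y, MaskSpec.from_window(x, y))
            dp = detect_double_peak(_chrom(masked, x), truth.window)
            assert dp.valley[1] < dp.left_max[1]
            assert dp.valley[1] < dp.right_max[1]


class TestManualLegs:
    def test_manual_legs_match_automatic_on_clean_double_peak(self):
        x = np.arange(161, dtype=float)
        y = 60 * np.exp(-((x - 50) ** 2) / 100.0) + 60 * np.exp(-((x - 110) ** 2) / 100.0)
        chrom = _chrom(y)
        auto = detect_double_peak(chrom, PeakWindow(0, 160))
        manual = define_legs_manual(
            chrom,
            PeakWindow(0, auto.left_max[0]),
            PeakWindow(auto.right_max[0], 160),
        )
        assert manual.detection_mode == "manual"
        np.testing.assert_allclose(
            np.sort(manual.left_leg.positions), np.sort(auto.left_leg.positions)
        )
        np.testing.assert_allclose(
            np.sort(manual.right_leg.positions), np.sort(auto.right_leg.positions)
        )

    def test_overlapping_leg_windows_rejected(self):
        chrom = _chrom(np.ones(50))
        with pytest.raises(ParameterError):
            define_legs_manual(chrom, PeakWindow(0, 30), PeakWindow(20, 49))


class TestTrimLegs:
    def _double_peak(self, n_leg=100):
        x = np.arange(2 * n_leg + 21, dtype=float)
        c = (len(x) - 1) / 2
        y = 80 * np.exp(-((x - c) ** 2) / (0.8 * len(x)) ** 2) + 10
        y[int(c) - 10 : int(c) + 11] -= 15  # carve a valley
        return detect_double_peak(_chrom(y), PeakWindow(x[0], x[-1]))

    def test_coverage_one_is_identity(self):
        dp = self._double_peak()
        assert trim_legs(dp, 1.0) is dp

    def test_sigmoid_inflection_located_at_steepest_point(self):
        # logistic leg: inflection of 1/(1+exp(-(x-x0)/s)) is at x0
        x = np.arange(200, dtype=float)
        x0 = 60.0
        y = 100.0 / (1.0 + np.exp(-(x0 - x) / 12.0))  # descending leg from apex
        from halofit.peaks import LegSegment, _trim_one

        leg = LegSegment(positions=x, intensities=y)
        trimmed = _trim_one(leg, 0.3)
        assert trimmed.positions[0] == pytest.approx(x0, abs=1.0)

    def test_index_arithmetic_on_constructed_leg(self):
        # 100-sample leg, inflection forced at sample 30, coverage 0.5
        # -> 50 samples retained starting at sample 30
        from halofit.peaks import LegSegment, _trim_one

        x = np.arange(100, dtype=float)
        y = np.linspace(50, 10, 100)
        y[29:32] = [42, 35, 28]  # steepest central-difference slope at 30
        trimmed = _trim_one(LegSegment(positions=x, intensities=y), 0.5)
        assert len(trimmed) == 50
        assert trimmed.positions[0] == 30

    def test_too_short_leg_raises(self):
        from halofit.peaks import LegSegment, _trim_one

        leg = LegSegment(positions=np.arange(3.0), intensities=np.arange(3.0))
        with pytest.raises(DataError):
            _trim_one(leg, 0.5)

    def test_invalid_coverage_rejected(self):
        dp = self._double_peak()
        with pytest.raises(ParameterError):
            trim_legs(dp, 0.0)
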