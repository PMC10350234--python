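"""Background estimation, robust thresholding and density measurement.

The classification examples are checked against a literal brute-force
oracle that compares per-pixel distances to the robust maximum and to Q3,
independent of the vectorized threshold algebra.
"""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from innervaquant import quantify as qt
from innervaquant import simulate as sim
from innervaquant import denoise as dn
from innervaquant.errors import ValidationError, ZeroAreaError
from innervaquant.imgio import MarkerImage

from conftest import make_spec


def distance_oracle(values: np.ndarray, stats: qt.ThresholdStats) -> np.ndarray:
    """Literal reading of the rule: positive iff strictly closer to the
    robust maximum than to Q3."""
    if stats.robust_max == stats.q3:
        return np.zeros(values.shape, dtype=bool)
    out = np.zeros(values.shape, dtype=bool)
    it = np.nditer(values, flags=["multi_index"])
    for v in it:
        d_max = abs(stats.robust_max - float(v))
        d_q3 = abs(float(v) - stats.q3)
        out[it.multi_index] = d_max < d_q3
    return out


class TestEstimateBackground:
    def test_constant_collection(self):
        assert qt.estimate_background([0.3] * 8) == pytest.approx(0.3)

    def test_low_spectrum_median(self):
        values = [0.1] * 16 + [0.9] * 4
        assert qt.estimate_background(values) == pytest.approx(0.1)

    def test_low_side_outlier_removed(self):
        values = [0.0] + [0.1] * 15 + [0.9] * 4
        assert qt.estimate_background(values) == pytest.approx(0.1)

    def test_too_few_values(self):
        with pytest.raises(ValidationError):
            qt.estimate_background([0.1, 0.2, 0.3])


class TestSubtractBackground:
    def test_zero_background_identity(self):
        img = MarkerImage(pixels=np.linspace(0, 1, 16).reshape(4, 4))
        out = qt.subtract_background(img, 0.0)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_exact_cancellation_and_floor(self):
        img = MarkerImage(pixels=np.full((3, 3), 0.3))
        assert np.all(qt.subtract_background(img, 0.3).pixels == 0.0)
        assert np.all(qt.subtract_background(img, 0.5).pixels == 0.0)

    def test_negative_background_rejected(self):
        with pytest.raises(ValidationError):
            qt.subtract_background(MarkerImage(pixels=np.zeros((2, 2))), -0.1)

    def test_metadata_preserved(self):
        img = MarkerImage(pixels=np.full((2, 2), 0.5), channel_name="red",
                          pixel_size_um=0.5)
        out = qt.subtract_background(img, 0.1)
        assert out.channel_name == "red" and out.pixel_size_um == 0.5


class TestThresholdStats:
    def test_linear_interpolation_quantiles(self):
        values = np.arange(1, 12) * 0.01  # 0.01 .. 0.11
        s = qt.compute_threshold_stats(values)
        assert s.median == pytest.approx(0.06)
        assert s.q1 == pytest.approx(0.035)
        assert s.q3 == pytest.approx(0.085)
        assert s.iqr == pytest.approx(0.05)
        assert s.robust_max == pytest.approx(0.11)  # fence 0.16 keeps the max
        assert s.threshold == pytest.approx((0.11 + 0.085) / 2)

    def test_degenerate_mostly_zeros(self):
        values = np.array([0.0] * 97 + [0.5, 0.6, 0.9])
        s = qt.compute_threshold_stats(values)
        assert s.q3 == 0.0 and s.upper_fence == 0.0
        assert s.robust_max == 0.0 and s.threshold == 0.0
        assert s.degenerate

    def test_constant_values(self):
        s = qt.compute_threshold_stats([0.4] * 10)
        assert s.q3 == s.robust_max == s.threshold == pytest.approx(0.4)
        assert s.degenerate

    def test_invariant_ordering(self, rng):
        values = rng.random(1000)
        s = qt.compute_threshold_stats(values)
        assert s.minimum <= s.q1 <= s.median <= s.q3 <= s.maximum
        assert s.q3 <= s.robust_max <= s.maximum
        assert s.threshold >= s.q3

    def test_order_invariance(self, rng):
        values = rng.random(513)
        a = qt.compute_threshold_stats(values)
        b = qt.compute_threshold_stats(values[rng.permutation(513)])
        assert a == b

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            qt.compute_threshold_stats([0.1, np.nan, 0.3, 0.4])


class TestClassifyPositive:
    def _stats(self, values):
        return qt.compute_threshold_stats(np.asarray(values))

    def test_value_at_robust_max_positive(self, rng):
        values = np.concatenate([rng.random(100) * 0.2, [0.5]])
        s = self._stats(values)
        assert s.robust_max > s.q3
        assert qt.classify_positive(np.array([[s.robust_max]]), s)[0, 0]

    def test_value_at_q3_negative(self, rng):
        s = self._stats(rng.random(100))
        assert not qt.classify_positive(np.array([[s.q3]]), s)[0, 0]

    def test_exact_midpoint_tie_is_negative(self, rng):
        s = self._stats(rng.random(100))
        mid = (s.robust_max + s.q3) / 2.0
        assert not qt.classify_positive(np.array([[mid]]), s)[0, 0]

    def test_degenerate_returns_all_false_with_warning(self, caplog):
        s = self._stats([0.2] * 50)
        with caplog.at_level(logging.WARNING, logger="innervaquant.quantify"):
            mask = qt.classify_positive(np.full((5, 5), 0.9), s)
        assert not mask.any()
        assert any("degenerate" in r.message for r in caplog.records)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_distance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.random((60, 60)) ** 3  # skewed like real sections
        s = qt.compute_threshold_stats(values)
        np.testing.assert_array_equal(
            qt.classify_positive(values, s), distance_oracle(values, s)
        )

    @given(hst.integers(min_value=0, max_value=10**6))
    @settings(max_examples=20, deadline=None)
    def test_monotone_in_pixel_value(self, seed):
        """Raising one pixel's value never flips it positive -> negative."""
        rng = np.random.default_rng(seed)
        values = rng.random(64)
        s = qt.compute_threshold_stats(values)
        v = rng.random()
        higher = min(1.0, v + rng.random() * (1 - v))
        arr = np.array([[v, higher]])
        mask = qt.classify_positive(arr, s)
        assert not (mask[0, 0] and not mask[0, 1])

    def test_scale_equivariance(self, rng):
        values = rng.random(400)
        k = 0.37
        a = qt.compute_threshold_stats(values)
        b = qt.compute_threshold_stats(values * k)
        assert b.q3 == pytest.approx(k * a.q3)
        assert b.robust_max == pytest.approx(k * a.robust_max)
        assert b.threshold == pytest.approx(k * a.threshold)
        np.testing.assert_array_equal(
            qt.classify_positive(values, a), qt.classify_positive(values * k, b)
        )


class TestCountPositive:
    def _masks(self):
        region = np.ones((6, 6), dtype=int)
        layer = np.zeros((6, 6), dtype=int)
        layer[1:3] = 1
        layer[3:6] = 2
        return region, layer

    def test_empty_and_saturated(self):
        region, layer = self._masks()
        empty = np.zeros((6, 6), dtype=bool)
        assert qt.count_positive(empty, region, layer, 1, "whole") == (0, 30)
        full = np.ones((6, 6), dtype=bool)
        assert qt.count_positive(full, region, layer, 1, "whole") == (30, 30)

    def test_zero_area_error(self):
        region, layer = self._masks()
        with pytest.raises(ZeroAreaError):
            qt.count_positive(np.zeros((6, 6), bool), region, layer, 4, "whole")

    def test_truth_mask_recovers_ground_truth_count(self, day15_section):
        s = day15_section
        n, area = qt.count_positive(
            s.truth_mask, s.labels.region_mask, s.labels.layer_mask, 1, 2
        )
        cell = (s.labels.region_mask == 1) & (s.labels.layer_mask == 2)
        assert n == int(s.truth_mask[cell].sum())


class TestDensityRecords:
    def test_zero_fiber_section_has_near_zero_density(self):
        """With no fibers the only positives are rare debris pixels."""
        section = sim.generate_section(make_spec(0.0, seed=11))
        img = dn.median_fallback(section.image, 1)
        records = qt.density_records(img, section.labels, "s", 15)
        assert all(r.density <= 0.01 for r in records)

    def test_additivity_epidermis_plus_dermis(self, day15_section):
        records = qt.density_records(
            dn.median_fallback(day15_section.image, 1),
            day15_section.labels, "s", 15,
        )
        by = {(r.region, r.layer): r for r in records}
        for region in {r.region for r in records}:
            whole = by[(region, "whole")]
            epi = by.get((region, "epidermis"))
            derm = by.get((region, "dermis"))
            if epi and derm:
                assert whole.positive_pixels == epi.positive_pixels + derm.positive_pixels
                assert whole.area_pixels == epi.area_pixels + derm.area_pixels

    @pytest.mark.parametrize("fraction", [0.02, 0.18])
    def test_parameter_recovery(self, fraction):
        section = sim.generate_section(make_spec(fraction, seed=23))
        img = dn.median_fallback(section.image, 1)
        records = qt.density_records(img, section.labels, "s", 15)
        whole = next(
            r for r in records if r.region == "wound_bed" and r.layer == "whole"
        )
        tol = max(0.25 * fraction, 0.01)
        assert abs(whole.density - fraction) <= tol

    def test_noise_free_no_denoiser_recovery(self):
        section = sim.generate_section(make_spec(0.02, seed=31, noise_sigma=0.0))
        records = qt.density_records(section.image, section.labels, "s", 15)
        whole = next(
            r for r in records if r.region == "wound_bed" and r.layer == "whole"
        )
        assert 0.015 <= whole.density <= 0.025

    def test_control_floor_raises_threshold(self, day15_section):
        img = dn.median_fallback(day15_section.image, 1)
        _, base = qt.density_records(
            img, day15_section.labels, "s", 15, return_stats=True
        )
        _, raised = qt.density_records(
            img, day15_section.labels, "s", 15,
            control_floor_value=0.9, return_stats=True,
        )
        assert raised.threshold == 0.9 > base.threshold


class TestControlFloor:
    def test_all_zero_control(self):
        img = MarkerImage(pixels=np.zeros((32, 32)))
        assert qt.control_floor(img) == 0.0

    def test_constant_control_cancels(self):
        img = MarkerImage(pixels=np.full((32, 32), 0.2))
        assert qt.control_floor(img) == 0.0

    def test_gaussian_control_matches_normal_quantile(self):
        rng = np.random.default_rng(8)
        pixels = np.clip(rng.normal(0.0, 0.05, size=(400, 250)), 0.0, 1.0)
        floor = qt.control_floor(MarkerImage(pixels=pixels))
        assert floor == pytest.approx(2.3263 * 0.05, abs=0.01)
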