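"""Waviness statistic: defining formula, hierarchical averaging, tests."""
import numpy as np
import pytest

from sclerashg.errors import (
    DegenerateFiberError,
    DegenerateTestError,
    InvalidParameterError,
    UndefinedStatisticError,
)
from sclerashg.geometry import Polyline
from sclerashg.waviness import (
    FiberMeasurement,
    compare_waviness,
    condition_waviness,
    fiber_waviness,
    image_mean_waviness,
    waviness_percent,
)


def _m(image_id, fiber_id, wav):
    return FiberMeasurement(image_id, fiber_id, arc=wav * 100.0, chord=100.0, waviness=wav)


class TestFiberWaviness:
    def test_straight_segment_is_one(self):
        assert fiber_waviness(Polyline(np.array([(0, 0), (10, 0)], float))) == 1.0

    def test_triangle_example(self):
        p = Polyline(np.array([(0, 0), (1, 1), (2, 0)], float))
        assert fiber_waviness(p) == pytest.approx(np.sqrt(2), abs=1e-6)

    def test_degenerate_chord_rejected(self):
        loop = Polyline(np.array([(0, 0), (5, 5), (0.1, 0.0)], float))
        with pytest.raises(DegenerateFiberError):
            fiber_waviness(loop)

    def test_never_below_one(self):
        with pytest.raises(InvalidParameterError):
            FiberMeasurement("i", "f", arc=90.0, chord=100.0, waviness=0.9)


class TestHierarchicalAveraging:
    def test_constant_fibers(self):
        fibers = [_m("img1", f"f{i}", 1.2) for i in range(10)]
        assert image_mean_waviness(fibers) == pytest.approx(1.2)

    def test_two_fiber_mean(self):
        assert image_mean_waviness([_m("i", "a", 1.1), _m("i", "b", 1.3)]) == pytest.approx(1.2)

    def test_mixed_images_rejected(self):
        with pytest.raises(InvalidParameterError):
            image_mean_waviness([_m("i1", "a", 1.1), _m("i2", "b", 1.3)])

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            image_mean_waviness([])

    def test_off_nominal_count_warns(self, caplog):
        with caplog.at_level("WARNING"):
            image_mean_waviness([_m("i", "a", 1.1), _m("i", "b", 1.3)])
        assert "2 fiber measurements" in caplog.text

    def test_condition_summary(self):
        c = condition_waviness([1.2] * 10, "control")
        assert (c.condition_mean, c.condition_sd) == (pytest.approx(1.2), pytest.approx(0.0))
        c2 = condition_waviness([1.1, 1.3], "control")
        assert c2.condition_mean == pytest.approx(1.2)
        assert c2.condition_sd == pytest.approx(0.141421, abs=1e-6)
        with pytest.raises(InvalidParameterError):
            condition_waviness([1.2], "control")

    def test_hierarchical_equals_flat_only_with_equal_counts(self):
        """Fibers->image->condition averaging matches the flat fiber mean
        exactly when every image holds the same number of fibers, and
        deviates otherwise."""
        balanced = {
            "a": [1.1, 1.3],
            "b": [1.2, 1.4],
        }
        img_means = [np.mean(v) for v in balanced.values()]
        flat = np.mean([w for v in balanced.values() for w in v])
        assert np.mean(img_means) == pytest.approx(flat)

        skewed = {"a": [1.1], "b": [1.2, 1.4, 1.6]}
        img_means = [np.mean(v) for v in skewed.values()]
        flat = np.mean([w for v in skewed.values() for w in v])
        assert np.mean(img_means) != pytest.approx(flat)


class TestWavinessPercent:
    def test_defining_formula_forty_millimolar(self):
        treated = condition_waviness([1.18, 1.198], "treated")  # mean 1.189
        control = condition_waviness([1.29, 1.31], "control")  # mean 1.300
        res = waviness_percent(treated, control)
        assert res.waviness_percent == pytest.approx(63.0, abs=1e-9)

    def test_defining_formula_four_hundred_millimolar(self):
        treated = condition_waviness([1.16, 1.17], "treated")  # mean 1.165
        control = condition_waviness([1.29, 1.31], "control")
        res = waviness_percent(treated, control)
        assert res.waviness_percent == pytest.approx(55.0, abs=1e-9)

    def test_equal_means_give_hundred_percent(self):
        treated = condition_waviness([1.28, 1.32], "treated")
        control = condition_waviness([1.29, 1.31], "control")
        res = waviness_percent(treated, control)
        assert res.waviness_percent == pytest.approx(100.0)

    def test_straight_controls_undefined(self):
        treated = condition_waviness([1.1, 1.2], "treated")
        control = condition_waviness([1.0, 1.0], "control")
        with pytest.raises(UndefinedStatisticError):
            waviness_percent(treated, control)

    def test_per_image_ratio_alternative(self):
        treated = condition_waviness([1.15, 1.21], "treated")
        control = condition_waviness([1.30, 1.30], "control")
        res = waviness_percent(treated, control, method="per-image-ratio")
        expected = np.mean([100 * 0.15 / 0.30, 100 * 0.21 / 0.30])
        assert res.waviness_percent == pytest.approx(expected)


class TestCompareWaviness:
    def test_identical_arms_p_one(self):
        assert compare_waviness([1.2, 1.3, 1.4], [1.2, 1.3, 1.4]) == 1.0

    def test_paired_t_closed_form(self):
        """Diffs {1,2,3}: t = 2/(1/sqrt(3)) = 3.4641, df = 2, p = 0.0742."""
        control = [10.0, 20.0, 30.0]
        treated = [11.0, 22.0, 33.0]
        p = compare_waviness(treated, control, paired=True)
        assert p == pytest.approx(0.0742, abs=2e-4)

    def test_constant_nonzero_differences_degenerate(self):
        with pytest.raises(DegenerateTestError):
            compare_waviness([2.0, 3.0], [1.0, 2.0])

    def test_unpaired_welch_mode(self):
        p = compare_waviness([1.1, 1.2, 1.15], [1.3, 1.35, 1.32], paired=False)
        assert 0.0 < p < 0.05

    def test_length_mismatch_rejected_when_paired(self):
        with pytest.raises(InvalidParameterError):
            compare_waviness([1.0, 2.0, 3.0], [1.0, 2.0])
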