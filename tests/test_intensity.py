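"""Histogram brightness readout, paired differences, mixed model."""
import numpy as np
import pandas as pd
import pytest
from numpy.random import default_rng

from sclerashg.errors import InvalidParameterError
from sclerashg.imgio import Image16
from sclerashg.intensity import (
    fit_random_intercept,
    image_histogram,
    mean_pixel_density,
    paired_intensity_analysis,
)


def _img(arr):
    return Image16(np.asarray(arr, dtype=np.uint16), bit_depth=12)


class TestHistogram:
    def test_constant_image_single_bin(self):
        h = image_histogram(_img(np.full((10, 10), 500)))
        assert h.mean == 500.0
        assert (h.counts > 0).sum() == 1
        assert h.counts.sum() == h.n_pixels == 100

    def test_two_by_two_mean(self):
        h = image_histogram(_img([[0, 100], [200, 300]]))
        assert h.mean == 150.0

    def test_histogram_mean_is_pixel_mean_exactly(self, rng):
        arr = rng.integers(0, 4096, size=(200, 200)).astype(np.uint16)
        img = _img(arr)
        assert image_histogram(img).mean == mean_pixel_density(img)
        assert mean_pixel_density(img) == float(arr.mean())


class TestPairedAnalysis:
    def test_identical_pairs_flagged_degenerate(self):
        img = _img(np.full((8, 8), 100))
        res = paired_intensity_analysis([(img, img), (img, img)])
        assert res.mean_difference == 0.0
        assert res.degenerate
        assert res.p_value == 1.0

    def test_requires_two_pairs(self):
        img = _img(np.full((8, 8), 100))
        with pytest.raises(InvalidParameterError):
            paired_intensity_analysis([(img, img)])

    def test_known_differences(self):
        pairs = [
            (_img(np.full((4, 4), 110)), _img(np.full((4, 4), 100))),
            (_img(np.full((4, 4), 130)), _img(np.full((4, 4), 100))),
            (_img(np.full((4, 4), 150)), _img(np.full((4, 4), 100))),
        ]
        res = paired_intensity_analysis(pairs)
        assert res.per_rabbit_differences == (10.0, 30.0, 50.0)
        assert res.mean_difference == pytest.approx(30.0)
        assert res.sd_difference == pytest.approx(20.0)


class TestMixedModel:
    def test_balanced_contrast_equals_mean_paired_difference(self):
        """GLS with a random intercept reduces to the simple mean of
        within-rabbit differences in the balanced two-condition design."""
        rng = default_rng(42)
        rows, diffs = [], []
        for r in range(8):
            b = rng.normal(0, 10)
            c = 500 + b + rng.normal(0, 5)
            t = 560 + b + rng.normal(0, 5)
            rows += [
                {"rabbit": f"r{r}", "condition": "control", "mean": c},
                {"rabbit": f"r{r}", "condition": "treated", "mean": t},
            ]
            diffs.append(t - c)
        fit = fit_random_intercept(pd.DataFrame(rows))
        est, se, p = fit.pairwise_contrasts[("treated", "control")]
        assert est == pytest.approx(np.mean(diffs), abs=1e-8)
        assert fit.rabbit_intercept_variance >= 0
        assert fit.residual_variance >= 0

    def test_noiseless_effects_recovered_exactly(self):
        rows = []
        for r in range(4):
            rows += [
                {"rabbit": f"r{r}", "condition": "0", "mean": 100.0},
                {"rabbit": f"r{r}", "condition": "40", "mean": 130.0},
                {"rabbit": f"r{r}", "condition": "400", "mean": 400.0},
            ]
        fit = fit_random_intercept(pd.DataFrame(rows))
        assert fit.reference == "0"
        assert fit.condition_effects["40"] == pytest.approx(30.0, abs=1e-6)
        assert fit.condition_effects["400"] == pytest.approx(300.0, abs=1e-6)

    def test_contrasts_antisymmetric(self):
        rng = default_rng(3)
        rows = []
        for r in range(6):
            b = rng.normal(0, 5)
            for cond, mu in (("0", 100), ("40", 160), ("400", 450)):
                rows.append(
                    {"rabbit": f"r{r}", "condition": cond, "mean": mu + b + rng.normal(0, 8)}
                )
        fit = fit_random_intercept(pd.DataFrame(rows))
        for (a, b_), (est, se, p) in fit.pairwise_contrasts.items():
            rev = fit.pairwise_contrasts[(b_, a)]
            assert est == pytest.approx(-rev[0], abs=1e-10)
            assert p == pytest.approx(rev[2], abs=1e-12)

    def test_single_rabbit_rejected(self):
        df = pd.DataFrame(
            [
                {"rabbit": "r0", "condition": "0", "mean": 1.0},
                {"rabbit": "r0", "condition": "40", "mean": 2.0},
            ]
        )
        with pytest.raises(InvalidParameterError):
            fit_random_intercept(df)

    def test_single_condition_rejected(self):
        df = pd.DataFrame(
            [
                {"rabbit": "r0", "condition": "0", "mean": 1.0},
                {"rabbit": "r1", "condition": "0", "mean": 2.0},
            ]
        )
        with pytest.raises(InvalidParameterError):
            fit_random_intercept(df)

    def test_wald_type_one_error_near_nominal(self):
        """Null simulation: with a comfortable number of animals the Wald
        contrast rejects at about the nominal 5% rate."""
        rng = default_rng(2024)
        k = 0
        n_sims = 100
        for _ in range(n_sims):
            rows = []
            for r in range(30):
                b = rng.normal(0, 10)
                rows += [
                    {"rabbit": f"r{r}", "condition": "control", "mean": 500 + b + rng.normal(0, 8)},
                    {"rabbit": f"r{r}", "condition": "treated", "mean": 500 + b + rng.normal(0, 8)},
                ]
            fit = fit_random_intercept(pd.DataFrame(rows))
            if fit.pairwise_contrasts[("treated", "control")][2] < 0.05:
                k += 1
        from scipy.stats import binom

        lo, hi = binom.ppf([0.025, 0.975], n_sims, 0.05)
        assert lo <= k <= hi
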