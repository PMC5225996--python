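"""Generator ground truth: centerline solver, renderer, condition sets,
Tm tables. The independent oracle for the sinusoid arc length is the
complete elliptic integral of the second kind."""
import math

import numpy as np
import pytest
from scipy.special import ellipe

from sclerashg.errors import InvalidParameterError
from sclerashg.geometry import arc_length, chord_length
from sclerashg.imgio import Image16
from sclerashg.intensity import mean_pixel_density
from sclerashg.synth import (
    FiberSpec,
    GeneratorConfig,
    NoiseModel,
    TmTableConfig,
    _sample_fiber_layout,
    generate_condition_set,
    generate_tm_table,
    get_preset,
    make_centerline,
    render_image,
)


class TestMakeCenterline:
    def test_straight_degenerate_case(self):
        p = make_centerline(1.0, 400.0, 0.0)
        assert arc_length(p) / chord_length(p) == pytest.approx(1.0, abs=1e-12)
        assert chord_length(p) == pytest.approx(400.0)

    @pytest.mark.parametrize("target", [1.05, 1.189, 1.30])
    def test_ratio_matches_target_and_elliptic_oracle(self, target):
        """Polygonal ratio hits the target within 1e-4, and the implied
        amplitude agrees with the closed-form elliptic-integral arc length."""
        length, cycles = 400.0, 2
        p = make_centerline(target, length, 0.0, phase=0.0)
        ratio = arc_length(p) / chord_length(p)
        assert ratio == pytest.approx(target, abs=1e-4)
        # independent oracle: mean of sqrt(1 + m^2 cos^2) over a period
        amp = (p.points[:, 1].max() - p.points[:, 1].min()) / 2.0
        m = amp * 2.0 * math.pi * cycles / length
        mm = m * m / (1.0 + m * m)
        continuous = 2.0 / math.pi * math.sqrt(1.0 + m * m) * ellipe(mm)
        assert continuous == pytest.approx(target, abs=5e-4)

    def test_impossible_target_rejected(self):
        with pytest.raises(InvalidParameterError):
            make_centerline(0.9, 400.0, 0.0)

    def test_orientation_preserves_ratio(self):
        a = make_centerline(1.25, 300.0, 0.0, phase=0.7)
        b = make_centerline(1.25, 300.0, 63.0, phase=0.7)
        ra = arc_length(a) / chord_length(a)
        rb = arc_length(b) / chord_length(b)
        assert ra == pytest.approx(rb, rel=1e-12)

    def test_dense_sampling(self):
        p = make_centerline(1.3, 400.0, 0.0)
        seg = np.diff(p.points, axis=0)
        assert np.hypot(seg[:, 0], seg[:, 1]).max() <= 1.0


class TestRenderImage:
    def test_empty_scene_is_constant(self):
        cfg = GeneratorConfig(
            name="t", image_size=(64, 64), background_level=500.0,
            noise_model=NoiseModel("none"),
        )
        img = render_image([], cfg)
        assert mean_pixel_density(img) == 500.0
        assert np.all(img.pixels == 500)

    def test_straight_flat_top_matches_pixel_count_arithmetic(self):
        """Image mean elevation equals peak * tube pixel count / n_pixels."""
        cfg = GeneratorConfig(
            name="t", image_size=(256, 256), background_level=100.0,
            noise_model=NoiseModel("none"), fiber_width=5.0, fiber_length=200.0,
        )
        pts = np.column_stack([np.linspace(20.0, 220.0, 401), np.full(401, 128.0)])
        from sclerashg.geometry import Polyline

        fiber = FiberSpec.from_centerline(Polyline(pts), 5.0, 400.0)
        img = render_image([fiber], cfg)
        count = int((img.pixels > 100).sum())
        # exact bookkeeping against the realized mask
        assert mean_pixel_density(img) == pytest.approx(
            100.0 + 400.0 * count / img.pixels.size, abs=1e-9
        )
        # and the mask itself matches w*L plus end caps within rounding
        analytic = 5.0 * 200.0 + math.pi * 5.0**2 / 4.0
        assert count == pytest.approx(analytic, rel=0.02)

    def test_determinism_bit_identical(self, small_intensity_config):
        cfg = small_intensity_config(seed=7)
        a = generate_condition_set(cfg)
        b = generate_condition_set(cfg)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.treated.pixels, pb.treated.pixels)
            assert np.array_equal(pa.control.pixels, pb.control.pixels)

    def test_container_overflow_rejected(self):
        with pytest.raises(InvalidParameterError):
            GeneratorConfig(
                name="t", background_level=500.0,
                fiber_intensity_offset_treated=4000.0,
            )


class TestConditionSets:
    def test_ground_truth_waviness_recomputes(self, small_intensity_config):
        cset = generate_condition_set(small_intensity_config(seed=3, n_rabbits=2))
        for pair in cset:
            for f in pair.treated_fibers + pair.control_fibers:
                ratio = arc_length(f.centerline) / chord_length(f.centerline)
                assert ratio == pytest.approx(f.true_waviness, abs=1e-6)

    def test_mean_difference_matches_analytic_expectation(self, small_intensity_config):
        """Grand mean of per-pair differences sits within 3 SE of the
        config's analytic expectation over 20 seeds."""
        diffs = []
        for seed in range(20):
            cfg = small_intensity_config(mean_difference=20.0, seed=seed, n_rabbits=4)
            assert cfg.analytic_mean_difference() == pytest.approx(20.0, abs=1e-9)
            for pair in generate_condition_set(cfg):
                diffs.append(
                    mean_pixel_density(pair.treated) - mean_pixel_density(pair.control)
                )
        arr = np.asarray(diffs)
        se = arr.std(ddof=1) / np.sqrt(arr.size)
        assert abs(arr.mean() - 20.0) <= 3 * se

    def test_doubling_fibers_doubles_mean_elevation(self):
        """Flat-top profiles: expected mean elevation is linear in fiber
        count (analytic pixel-count prediction) within 1%."""
        elevations = {6: [], 12: []}
        for n in (6, 12):
            for seed in range(5):
                cfg = GeneratorConfig(
                    name="t", image_size=(256, 256), background_level=100.0,
                    fiber_intensity_offset_control=800.0,
                    fiber_intensity_offset_treated=800.0,
                    noise_model=NoiseModel("none"), n_fibers_per_image=n,
                    fiber_width=6.0, fiber_length=80.0, seed=seed,
                    rabbit_intercept_sd=0.0, eye_intercept_sd=0.0,
                )
                rng = np.random.default_rng(seed)
                fibers = _sample_fiber_layout(cfg, 1.3, 800.0, rng)
                img = render_image(fibers, cfg)
                elevations[n].append(mean_pixel_density(img) - 100.0)
        ratio = np.mean(elevations[12]) / np.mean(elevations[6])
        assert ratio == pytest.approx(2.0, rel=0.01)

    def test_equal_arms_differ_only_by_placement(self, small_intensity_config):
        cfg = small_intensity_config(
            mean_difference=0.0, seed=5, n_rabbits=2,
            noise=NoiseModel("none"), rabbit_intercept_sd=0.0, eye_intercept_sd=0.0,
        )
        cset = generate_condition_set(cfg)
        for pair in cset:
            assert not np.array_equal(pair.treated.pixels, pair.control.pixels)
            d = mean_pixel_density(pair.treated) - mean_pixel_density(pair.control)
            assert abs(d) < 1.0  # same analytic coverage, placement jitter only

    def test_rejects_single_rabbit(self, small_intensity_config):
        with pytest.raises(InvalidParameterError):
            generate_condition_set(small_intensity_config(n_rabbits=1))


class TestTmTables:
    def test_noise_free_shift_map_is_exact(self):
        cfg = get_preset("cfg-tm-40-map", noise_sd=0.0, seed=1)
        table = generate_tm_table(cfg)
        d = table.assign(diff=table.treated_tm - table.control_tm)
        by = d.groupby("sector")["diff"].mean()
        for s in (1, 2, 3):
            assert by[s] == pytest.approx(3.4, abs=1e-12)
        for s in range(4, 17):
            assert by[s] == pytest.approx(0.0, abs=1e-12)

    def test_null_mean_shrinks_with_n(self):
        small = generate_tm_table(TmTableConfig(n_rabbits=3, noise_sd=1.0, seed=2))
        big = generate_tm_table(TmTableConfig(n_rabbits=200, noise_sd=1.0, seed=2))
        mean_small = (small.treated_tm - small.control_tm).mean()
        mean_big = (big.treated_tm - big.control_tm).mean()
        assert abs(mean_big) < 0.2
        assert abs(mean_big) < abs(mean_small) + 0.2

    def test_reproducible_under_seed(self):
        cfg = TmTableConfig(n_rabbits=4, noise_sd=0.7, seed=99)
        assert generate_tm_table(cfg).equals(generate_tm_table(cfg))

    def test_shift_keys_validated(self):
        with pytest.raises(InvalidParameterError):
            TmTableConfig(sector_shifts={0: 1.0})


def test_preset_registry_round_trip():
    cfg = get_preset("cfg-int-400")
    assert cfg.analytic_mean_difference() == pytest.approx(361.4, abs=1e-9)
    wav = get_preset("cfg-wav-400")
    assert wav.waviness_treated == pytest.approx(1.165)
    with pytest.raises(InvalidParameterError):
        get_preset("cfg-nope")
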