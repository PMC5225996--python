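import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sclerashg.geometry import transform
from sclerashg.synth import (
    FiberSpec,
    GeneratorConfig,
    NoiseModel,
    make_centerline,
    render_image,
)

settings.register_profile(
    "fixed",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def single_fiber_scene():
    """Factory: one in-bounds fiber of known waviness rendered noise-free
    (unless a noise model is given), returning (image, fiber, config)."""

    def build(
        waviness: float,
        orientation_deg: float = 20.0,
        phase: float = 1.0,
        width: float = 8.0,
        peak: float = 1800.0,
        length: float = 400.0,
        noise: str = "none",
        sigma: float = 20.0,
        image_size: tuple = (640, 640),
    ):
        base = make_centerline(waviness, length, orientation_deg, phase=phase)
        pts = base.points
        centered = transform(
            base,
            translation=(
                (image_size[1] - (pts[:, 0].max() - pts[:, 0].min())) / 2 - pts[:, 0].min(),
                (image_size[0] - (pts[:, 1].max() - pts[:, 1].min())) / 2 - pts[:, 1].min(),
            ),
        )
        cfg = GeneratorConfig(
            name="scene",
            image_size=image_size,
            background_level=150.0,
            fiber_intensity_offset_control=peak,
            fiber_intensity_offset_treated=peak,
            noise_model=NoiseModel(noise, sigma),
            n_fibers_per_image=1,
            fiber_width=width,
            fiber_length=length,
        )
        fiber = FiberSpec.from_centerline(centered, width, peak)
        img = render_image([fiber], cfg)
        return img, fiber, cfg

    return build


@pytest.fixture
def small_intensity_config():
    """Factory for a fast, small-image brightness preset with the treated
    peak re-derived so the analytic mean difference is preserved."""
    from sclerashg.synth import make_intensity_preset

    def build(mean_difference: float = 20.0, seed: int = 0, **kw):
        kw.setdefault("image_size", (192, 192))
        kw.setdefault("n_fibers", 6)
        kw.setdefault("fiber_width", 6.0)
        kw.setdefault("fiber_length", 70.0)
        return make_intensity_preset(
            "test-int", mean_difference, seed=seed, **kw
        )

    return build
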