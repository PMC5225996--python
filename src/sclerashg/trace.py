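"""Seeded centerline tracing of bright curvilinear fibers.

The original measurements were made by hand with a mouse-driven drawing
tool; this module replaces that step with a deterministic bidirectional
ridge follower so the measurement is reproducible. From a seed point on a
fiber, the tracer alternately advances a fixed step along the current
direction and re-centers on the intensity-weighted centroid along the local
normal, stopping at the image border, an intensity drop below a fraction of
the seed intensity, a turn-limit violation, or a step cap.

Sub-pixel intensities are bilinear. The initial direction comes from the
principal axis of the local gradient structure tensor (the standard
orientation estimate for ridge-like structures), with ties broken toward
the image x-axis.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .errors import InvalidParameterError, SeedNotOnFiberError, TraceFailedError
from .geometry import Polyline
from .imgio import Image16


@dataclass(frozen=True)
class TraceParams:
    """Tuning knobs of the ridge follower (all lengths in pixels)."""

    step_px: float = 2.0
    normal_halfwidth_px: float = 12.0  # ~1.5x a typical fiber width
    stop_intensity_fraction: float = 0.5
    max_turn_deg: float = 30.0
    max_steps: int = 2000
    min_seed_contrast: float = 50.0  # counts above background to accept a seed
    direction_inertia: float = 0.3  # weight of the previous direction
    # centered moving-average window (points) applied to the finished trace;
    # suppresses sub-pixel interpolation jitter that otherwise inflates the
    # polygonal arc length. 1 disables smoothing.
    smooth_window: int = 3

    def __post_init__(self) -> None:
        if self.step_px <= 0:
            raise InvalidParameterError("step_px must be positive")
        if not 0.0 < self.stop_intensity_fraction < 1.0:
            raise InvalidParameterError("stop_intensity_fraction must be in (0, 1)")
        if self.normal_halfwidth_px <= 0 or self.max_steps < 1:
            raise InvalidParameterError("invalid tracing parameters")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise InvalidParameterError("smooth_window must be odd and >= 1")


def _interp(pixels: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Bilinear image values at (x, y) points; edge-clamped."""
    pts = np.atleast_2d(pts)
    return map_coordinates(pixels, [pts[:, 1], pts[:, 0]], order=1, mode="nearest")


def _initial_direction(pixels: np.ndarray, seed: np.ndarray, window: float) -> np.ndarray:
    """Ridge direction from the structure tensor of a local window.

    The eigenvector of the *smaller* eigenvalue points along the ridge
    (gradients of a bright line are perpendicular to it). Near-isotropic
    neighborhoods fall back to the +x axis.
    """
    r = int(math.ceil(window))
    h, w = pixels.shape
    x0, x1 = max(int(seed[0]) - r, 0), min(int(seed[0]) + r + 1, w)
    y0, y1 = max(int(seed[1]) - r, 0), min(int(seed[1]) + r + 1, h)
    patch = gaussian_filter(pixels[y0:y1, x0:x1], 1.5)
    gy, gx = np.gradient(patch)
    jxx, jxy, jyy = (gx * gx).sum(), (gx * gy).sum(), (gy * gy).sum()
    tensor = np.array([[jxx, jxy], [jxy, jyy]])
    vals, vecs = np.linalg.eigh(tensor)
    if vals[1] <= 0 or (vals[1] - vals[0]) / vals[1] < 1e-3:
        return np.array([1.0, 0.0])
    d = vecs[:, 0]  # eigenvector of the smaller eigenvalue
    if d[0] < 0 or (d[0] == 0 and d[1] < 0):
        d = -d
    return d / np.hypot(d[0], d[1])


def trace_fiber(
    img: Image16, seed_point: tuple[float, float], params: TraceParams | None = None
) -> Polyline:
    """Trace the fiber under `seed_point` in both directions.

    Returns the concatenated centerline polyline. Raises SeedNotOnFiberError
    if the seed sits on background and TraceFailedError for a degenerate
    trace. Deterministic: same image, seed and params give the same result.
    """
    params = params or TraceParams()
    pixels = img.pixels.astype(float)
    h, w = pixels.shape
    seed = np.asarray(seed_point, dtype=float)
    if not (0 <= seed[0] <= w - 1 and 0 <= seed[1] <= h - 1):
        raise InvalidParameterError("seed point outside the image")
    background = float(np.median(pixels))
    seed_val = float(_interp(pixels, seed)[0])
    if seed_val - background < params.min_seed_contrast:
        raise SeedNotOnFiberError(
            f"seed intensity {seed_val:.1f} not above background {background:.1f}"
        )
    stop_level = background + params.stop_intensity_fraction * (seed_val - background)
    hw = params.normal_halfwidth_px
    offsets = np.linspace(-hw, hw, int(4 * hw) + 1)
    cos_limit = math.cos(math.radians(params.max_turn_deg))

    # centroid over a short stack of parallel normal lines: averaging along
    # the tangent suppresses the bilinear-interpolation moire that a single
    # line shows at oblique orientations
    line_shifts = np.array([-1.0, 0.0, 1.0])
    max_shift = 0.45 * hw

    def recenter(point: np.ndarray, direction: np.ndarray) -> np.ndarray | None:
        normal = np.array([-direction[1], direction[0]])
        base = point[None, :] + offsets[:, None] * normal[None, :]
        num = 0.0
        den = 0.0
        for shift in line_shifts:
            samples = base + shift * direction[None, :]
            weights = np.clip(_interp(pixels, samples) - background, 0.0, None)
            num += float(offsets @ weights)
            den += float(weights.sum())
        if den <= 0:
            return None
        delta = float(np.clip(num / den, -max_shift, max_shift))
        return point + delta * normal

    d0 = _initial_direction(pixels, seed, 2.0 * hw)
    start = recenter(seed, d0)
    if start is None:
        raise SeedNotOnFiberError("no ridge mass around the seed point")

    def half_trace(direction: np.ndarray) -> list[np.ndarray]:
        pts: list[np.ndarray] = []
        p, d = start.copy(), direction.copy()
        prev_step_dir = direction.copy()
        for _ in range(params.max_steps):
            q = p + params.step_px * d
            if not (1.0 <= q[0] <= w - 2 and 1.0 <= q[1] <= h - 2):
                break
            # intensity gate before re-centering: past the fiber tip the
            # centroid would otherwise slide around the end cap and U-turn
            if float(_interp(pixels, q)[0]) < stop_level:
                break
            centered = recenter(q, d)
            if centered is None:
                break
            q = centered
            if not (1.0 <= q[0] <= w - 2 and 1.0 <= q[1] <= h - 2):
                break
            if float(_interp(pixels, q)[0]) < stop_level:
                break
            step_vec = q - p
            norm = float(np.hypot(step_vec[0], step_vec[1]))
            if norm == 0.0:
                break
            nd = step_vec / norm
            # turn limit against the last realized step (the smoothed
            # direction lags on curves and would trip the limit spuriously)
            if float(nd @ prev_step_dir) < cos_limit:
                break
            pts.append(q)
            p = q
            prev_step_dir = nd
            mix = (1.0 - params.direction_inertia) * nd + params.direction_inertia * d
            d = mix / np.hypot(mix[0], mix[1])
        return pts

    forward = half_trace(d0)
    backward = half_trace(-d0)
    points = backward[::-1] + [start] + forward
    if len(points) < 2:
        raise TraceFailedError("trace produced fewer than 2 points")
    return Polyline(
        _smooth_points(np.array(points), params.smooth_window), img.pixel_size_um
    )


def _smooth_points(pts: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average over interior points; endpoints untouched."""
    if window <= 1 or len(pts) <= window:
        return pts
    kernel = np.full(window, 1.0 / window)
    half = window // 2
    out = pts.copy()
    out[half : len(pts) - half, 0] = np.convolve(pts[:, 0], kernel, mode="valid")
    out[half : len(pts) - half, 1] = np.convolve(pts[:, 1], kernel, mode="valid")
    return out


def select_seeds(
    img: Image16,
    n: int = 10,
    min_separation_px: float = 40.0,
    smooth_sigma: float = 2.0,
    grid_stride: int = 8,
) -> np.ndarray:
    """Deterministic seed proposals for real images without a manifest:
    the n strongest smoothed-intensity grid points subject to a minimum
    mutual separation. Returns an (n, 2) array of (x, y) points."""
    sm = gaussian_filter(img.pixels.astype(float), smooth_sigma)
    ys, xs = np.mgrid[
        grid_stride // 2 : sm.shape[0] : grid_stride,
        grid_stride // 2 : sm.shape[1] : grid_stride,
    ]
    cand = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    scores = sm[ys.ravel(), xs.ravel()]
    order = np.argsort(scores)[::-1]
    chosen: list[np.ndarray] = []
    for idx in order:
        p = cand[idx]
        if all(np.hypot(*(p - q)) >= min_separation_px for q in chosen):
            chosen.append(p)
            if len(chosen) == n:
                break
    return np.array(chosen)
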