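"""Polyline primitives.

A traced fiber centerline is an ordered sequence of sub-pixel 2-D points.
The two length measurements taken on it — the arc length along the trace and
the straight end-to-end chord — are the inputs of the waviness ratio.

Coordinate convention (used package-wide): a point is (x, y) = (column, row),
0-based, with pixel centers at integer coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError


@dataclass(frozen=True)
class Polyline:
    """Ordered sequence of >=2 sub-pixel 2-D points.

    Parameters
    ----------
    points
        Array of shape (n, 2) with columns (x, y). Consecutive points must be
        distinct and all coordinates finite.
    pixel_size_um
        Physical size of one pixel; lengths are reported in px * pixel_size.
    """

    points: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise InvalidParameterError("a polyline needs >=2 points of shape (n, 2)")
        if not np.all(np.isfinite(pts)):
            raise InvalidParameterError("polyline coordinates must be finite")
        seg = np.diff(pts, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0.0):
            raise InvalidParameterError("consecutive polyline points must be distinct")
        if not self.pixel_size_um > 0:
            raise InvalidParameterError("pixel_size_um must be positive")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]


def arc_length(p: Polyline) -> float:
    """Sum of Euclidean segment lengths, times the pixel size."""
    seg = np.diff(p.points, axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum() * p.pixel_size_um)


def chord_length(p: Polyline) -> float:
    """Straight-line distance between the first and last points, times pixel size."""
    d = p.points[-1] - p.points[0]
    return float(np.hypot(d[0], d[1]) * p.pixel_size_um)


def resample_polyline(p: Polyline, spacing_px: float) -> Polyline:
    """Arc-length-uniform resampling; the two endpoints are preserved exactly."""
    if not spacing_px > 0:
        raise InvalidParameterError("spacing_px must be positive")
    seg = np.diff(p.points, axis=0)
    cum = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    total = cum[-1]
    n = max(int(round(total / spacing_px)), 1) + 1
    t = np.linspace(0.0, total, n)
    x = np.interp(t, cum, p.points[:, 0])
    y = np.interp(t, cum, p.points[:, 1])
    pts = np.column_stack([x, y])
    pts[0] = p.points[0]
    pts[-1] = p.points[-1]
    # drop accidental duplicates produced by very coarse spacing
    keep = np.concatenate([[True], np.any(np.diff(pts, axis=0) != 0.0, axis=1)])
    pts = pts[keep]
    if pts.shape[0] < 2:
        raise InvalidParameterError("resampling collapsed the polyline to a point")
    return Polyline(pts, p.pixel_size_um)


def transform(
    p: Polyline,
    rotation_deg: float = 0.0,
    translation: tuple[float, float] = (0.0, 0.0),
    scale: float = 1.0,
) -> Polyline:
    """Similarity transform (rotate about origin, scale, then translate)."""
    th = np.deg2rad(rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    pts = scale * (p.points @ rot.T) + np.asarray(translation, dtype=float)
    return Polyline(pts, p.pixel_size_um)
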