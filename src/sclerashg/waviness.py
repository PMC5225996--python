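"""The fiber-bundle waviness statistic and its significance tests.

Waviness of a traced fiber is the arc-length-to-chord-length ratio
(>= 1; exactly 1 for a straight fiber). Measurements are averaged
hierarchically — the ~10 fibers within an image field first, then the ~10
image fields within a condition — and the treatment effect is summarized as

    Waviness-% = 100 * (W_treated - 1) / (W_control - 1),

the residual waviness of treated fibers relative to the paired controls
(lower = straighter). Significance uses a two-sided paired t-test on
image-level means by default (images are paired by animal), with a Welch
two-sample alternative for unpaired designs. alpha = 0.05 throughout.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    DegenerateFiberError,
    DegenerateTestError,
    InvalidParameterError,
    UndefinedStatisticError,
)
from .geometry import Polyline, arc_length, chord_length

logger = logging.getLogger(__name__)

NOMINAL_FIBERS_PER_IMAGE = 10


@dataclass(frozen=True)
class FiberMeasurement:
    """Arc, chord and their ratio for one traced fiber."""

    image_id: str
    fiber_id: str
    arc: float
    chord: float
    waviness: float

    def __post_init__(self) -> None:
        if self.waviness < 1.0 - 1e-9:
            raise InvalidParameterError("waviness below 1 (arc < chord?)")


@dataclass(frozen=True)
class ConditionWaviness:
    """Hierarchical waviness summary for one condition arm.

    condition_mean is the mean of the per-image means (the image, not the
    fiber, is the replication unit); condition_sd is the sample SD over
    images (n-1 denominator).
    """

    condition: str
    per_image_means: tuple[float, ...]
    condition_mean: float
    condition_sd: float


@dataclass(frozen=True)
class WavinessPercentResult:
    treated: ConditionWaviness
    control: ConditionWaviness
    waviness_percent: float
    p_value: float


def fiber_waviness(p: Polyline, chord_eps_px: float = 1.0) -> float:
    """Arc/chord ratio of a polyline; >= 1 up to numerical tolerance."""
    chord = chord_length(p)
    if chord <= chord_eps_px * p.pixel_size_um:
        raise DegenerateFiberError(f"chord {chord:.3g} below {chord_eps_px} px")
    return arc_length(p) / chord


def measure_fiber(p: Polyline, image_id: str, fiber_id: str) -> FiberMeasurement:
    """Package arc, chord and waviness of one trace."""
    return FiberMeasurement(
        image_id=image_id,
        fiber_id=fiber_id,
        arc=arc_length(p),
        chord=chord_length(p),
        waviness=fiber_waviness(p),
    )


def image_mean_waviness(fibers: list[FiberMeasurement]) -> float:
    """Arithmetic mean of fiber waviness within one image field."""
    if not fibers:
        raise InvalidParameterError("no fiber measurements")
    ids = {f.image_id for f in fibers}
    if len(ids) != 1:
        raise InvalidParameterError(f"measurements from multiple images: {sorted(ids)}")
    if len(fibers) != NOMINAL_FIBERS_PER_IMAGE:
        logger.warning(
            "image %s has %d fiber measurements (nominal %d)",
            fibers[0].image_id,
            len(fibers),
            NOMINAL_FIBERS_PER_IMAGE,
        )
    return float(np.mean([f.waviness for f in fibers]))


def condition_waviness(image_means, condition: str) -> ConditionWaviness:
    """Mean and sample SD over image-level means for one condition arm."""
    vals = np.asarray(list(image_means), dtype=float)
    if vals.size < 2:
        raise InvalidParameterError("need >=2 image-level means per condition")
    return ConditionWaviness(
        condition=condition,
        per_image_means=tuple(float(v) for v in vals),
        condition_mean=float(vals.mean()),
        condition_sd=float(vals.std(ddof=1)),
    )


def compare_waviness(treated_image_means, control_image_means, paired: bool = True) -> float:
    """Two-sided p-value comparing arm image means.

    Paired t-test when images are paired by animal (the default in this
    paired-eye design), otherwise Welch's two-sample test. All-zero paired
    differences yield p = 1 (no effect, no evidence); zero-variance nonzero
    differences are degenerate and raise.
    """
    t_vals = np.asarray(list(treated_image_means), dtype=float)
    c_vals = np.asarray(list(control_image_means), dtype=float)
    if t_vals.size < 2 or c_vals.size < 2:
        raise InvalidParameterError("need >=2 image means per arm")
    if paired:
        if t_vals.size != c_vals.size:
            raise InvalidParameterError("paired arms must have equal length")
        diffs = t_vals - c_vals
        if float(diffs.std(ddof=1)) == 0.0:
            if float(diffs.mean()) == 0.0:
                return 1.0
            raise DegenerateTestError("zero-variance nonzero paired differences")
        return float(stats.ttest_rel(t_vals, c_vals).pvalue)
    if float(t_vals.std(ddof=1)) == 0.0 and float(c_vals.std(ddof=1)) == 0.0:
        if float(t_vals.mean()) == float(c_vals.mean()):
            return 1.0
        raise DegenerateTestError("zero variance in both arms with unequal means")
    return float(stats.ttest_ind(t_vals, c_vals, equal_var=False).pvalue)


def waviness_percent(
    treated: ConditionWaviness,
    control: ConditionWaviness,
    paired: bool = True,
    method: str = "condition-mean",
) -> WavinessPercentResult:
    """Waviness-% = 100 (W_treated - 1)/(W_control - 1), with significance.

    method="condition-mean" evaluates the defining formula on the condition
    means (the literal definition); method="per-image-ratio" averages the
    ratio computed per paired image instead, exposed as an alternative
    aggregation. Undefined when control fibers are straight (denominator 0).
    """
    if control.condition_mean <= 1.0 + 1e-6:
        raise UndefinedStatisticError(
            "control waviness at 1: Waviness-% denominator vanishes"
        )
    if method == "condition-mean":
        pct = 100.0 * (treated.condition_mean - 1.0) / (control.condition_mean - 1.0)
    elif method == "per-image-ratio":
        t = np.asarray(treated.per_image_means)
        c = np.asarray(control.per_image_means)
        if t.size != c.size:
            raise InvalidParameterError("per-image-ratio method needs paired images")
        if np.any(c <= 1.0 + 1e-6):
            raise UndefinedStatisticError("a control image mean is at 1")
        pct = float(np.mean(100.0 * (t - 1.0) / (c - 1.0)))
    else:
        raise InvalidParameterError(f"unknown method {method!r}")
    p = compare_waviness(treated.per_image_means, control.per_image_means, paired=paired)
    return WavinessPercentResult(
        treated=treated, control=control, waviness_percent=float(pct), p_value=p
    )
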