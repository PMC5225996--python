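"""Histogram / mean-pixel-density analysis and the random-intercept model.

SHG brightness is read out as the mean of the full-bit-range intensity
histogram of each image ("mean pixel density"). Treatment effects are
estimated two ways, which agree exactly in the balanced paired case:

* per-animal treated-minus-control differences with a paired t-test;
* a linear mixed model of image means with fixed condition effects and a
  random intercept per animal (maximum likelihood, Wald inference), giving
  the pairwise dose contrasts (e.g. 40 vs 0 mM, 400 vs 0 mM).

Histogram bins are one intensity level wide and unnormalized, so the
histogram mean is identical to the direct pixel mean.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError
from .imgio import Image16


@dataclass(frozen=True)
class HistogramSummary:
    """Full-bit-range intensity histogram of one image (one bin per level)."""

    bin_edges: np.ndarray  # level boundaries, length n_levels + 1
    counts: np.ndarray
    mean: float
    n_pixels: int


@dataclass(frozen=True)
class PairedIntensityResult:
    per_rabbit_differences: tuple[float, ...]
    mean_difference: float
    sd_difference: float
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class MixedModelFit:
    """Fixed condition effects (vs the reference condition) and variance
    components of the random-intercept model."""

    reference: str
    condition_effects: dict
    effect_ses: dict
    pairwise_contrasts: dict  # (a, b) -> (estimate, se, p)
    rabbit_intercept_variance: float
    residual_variance: float
    n_rabbits: int


def image_histogram(img: Image16) -> HistogramSummary:
    """One bin per integer level over the full bit range; the histogram mean
    equals the direct pixel mean exactly (integer accumulation)."""
    n_levels = 1 << img.bit_depth
    counts = np.bincount(img.pixels.ravel(), minlength=n_levels)
    n_pixels = int(img.pixels.size)
    mean = float(
        (np.arange(n_levels, dtype=np.int64) * counts.astype(np.int64)).sum() / n_pixels
    )
    return HistogramSummary(
        bin_edges=np.arange(n_levels + 1, dtype=float) - 0.5,
        counts=counts,
        mean=mean,
        n_pixels=n_pixels,
    )


def mean_pixel_density(img: Image16) -> float:
    """Arithmetic mean of all pixel intensities (exact integer sum)."""
    return float(img.pixels.sum(dtype=np.int64) / img.pixels.size)


def paired_intensity_analysis(pairs: list[tuple[Image16, Image16]]) -> PairedIntensityResult:
    """Per-animal (treated mean - control mean) differences with a two-sided
    paired t-test. `pairs` is a list of (treated, control) images."""
    if len(pairs) < 2:
        raise InvalidParameterError("need >=2 treated/control pairs")
    diffs = np.array(
        [mean_pixel_density(t) - mean_pixel_density(c) for t, c in pairs]
    )
    sd = float(diffs.std(ddof=1))
    if sd == 0.0:
        # identical images in every pair: no variance to test against
        return PairedIntensityResult(
            per_rabbit_differences=tuple(diffs),
            mean_difference=float(diffs.mean()),
            sd_difference=0.0,
            p_value=1.0 if float(diffs.mean()) == 0.0 else float("nan"),
            degenerate=True,
        )
    t_res = stats.ttest_1samp(diffs, 0.0)
    return PairedIntensityResult(
        per_rabbit_differences=tuple(float(d) for d in diffs),
        mean_difference=float(diffs.mean()),
        sd_difference=sd,
        p_value=float(t_res.pvalue),
    )


def _order_conditions(conditions: pd.Series) -> list[str]:
    labels = [str(c) for c in pd.unique(conditions)]
    for ref in ("0", "control", "ctrl"):
        if ref in labels:
            labels.remove(ref)
            return [ref] + sorted(labels)
    labels.sort()
    return labels


def fit_random_intercept(
    observations: pd.DataFrame, reml: bool = False
) -> MixedModelFit:
    """Fit mean-brightness ~ condition with a random intercept per rabbit.

    `observations` needs columns rabbit, condition, mean. Estimation is
    maximum likelihood by default (REML via the switch); inference on the
    pairwise condition contrasts is Wald with no small-sample df correction.
    In the balanced paired design the fitted contrast coincides with the
    simple mean of within-rabbit differences.
    """
    import statsmodels.api as sm

    df = observations.copy()
    required = {"rabbit", "condition", "mean"}
    if not required.issubset(df.columns):
        raise InvalidParameterError(f"observations need columns {sorted(required)}")
    df["condition"] = df["condition"].astype(str)
    if df["rabbit"].nunique() < 2:
        raise InvalidParameterError(
            "random-intercept variance unidentifiable with a single rabbit"
        )
    order = _order_conditions(df["condition"])
    if len(order) < 2:
        raise InvalidParameterError("need >=2 conditions")
    reference, others = order[0], order[1:]
    exog = np.column_stack(
        [np.ones(len(df))] + [(df["condition"] == c).to_numpy(float) for c in others]
    )
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise InvalidParameterError("rank-deficient design (aliased conditions)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(df["mean"].to_numpy(float), exog, groups=df["rabbit"])
        fit = model.fit(reml=reml)
    params = np.asarray(fit.fe_params)
    cov = np.asarray(fit.cov_params())[: len(params), : len(params)]

    effects = {c: float(params[i + 1]) for i, c in enumerate(others)}
    ses = {c: float(np.sqrt(cov[i + 1, i + 1])) for i, c in enumerate(others)}

    def effect_vector(cond: str) -> np.ndarray:
        v = np.zeros(len(params))
        if cond != reference:
            v[1 + others.index(cond)] = 1.0
        return v

    contrasts = {}
    for a in order:
        for b in order:
            if a == b:
                continue
            vec = effect_vector(a) - effect_vector(b)
            est = float(vec @ params)
            se = float(np.sqrt(vec @ cov @ vec))
            z = est / se if se > 0 else np.inf * np.sign(est)
            p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
            contrasts[(a, b)] = (est, se, p)
    return MixedModelFit(
        reference=reference,
        condition_effects=effects,
        effect_ses=ses,
        pairwise_contrasts=contrasts,
        rabbit_intercept_variance=float(np.asarray(fit.cov_re)[0, 0]),
        residual_variance=float(fit.scale),
        n_rabbits=int(df["rabbit"].nunique()),
    )
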