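"""Robust thresholding and positive-pixel density quantification.

The classification rule, applied per image to the marker channel:

1. Estimate the background as the median of the "low spectrum" (values at or
   below Q1 of the whole-image intensity distribution) after discarding
   low-side Tukey outliers within that subset, and subtract it from every
   pixel (floored at 0).
2. On the background-subtracted values compute min, max, mean, median,
   Q1/Q3/IQR (linear-interpolation quantiles) and Tukey fences. The robust
   maximum is the largest value not exceeding the upper fence
   Q3 + 1.5*IQR (outliers above the fence are excluded from consideration).
3. A pixel is positive — counted as nerve-fiber signal — iff it lies strictly
   closer to the robust maximum than to Q3, i.e. iff its value exceeds the
   threshold (robust_max + Q3) / 2. Ties are negative.
4. Density per (region, layer) = positive pixels / cell area, a
   dimensionless pixel fraction.

Degenerate images (robust maximum equal to Q3, e.g. when three quarters of
the pixels share one value) yield zero positives with a logged warning
rather than an error: nearly-empty early-timepoint wound sections must not
abort a batch run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ValidationError, ZeroAreaError
from .imgio import DensityRecord, MarkerImage, RegionLabelSet

__all__ = [
    "ThresholdStats",
    "estimate_background",
    "subtract_background",
    "compute_threshold_stats",
    "classify_positive",
    "count_positive",
    "density_records",
    "control_floor",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdStats:
    """Per-image robust statistics driving positive-pixel classification."""

    minimum: float
    maximum: float
    mean: float
    median: float
    q1: float
    q3: float
    iqr: float
    lower_fence: float
    upper_fence: float
    robust_max: float
    background: float
    threshold: float
    n_pixels: int

    @property
    def degenerate(self) -> bool:
        """True when robust_max == q3 and no pixel can be positive."""
        return not self.robust_max > self.q3

    def as_dict(self) -> dict[str, float | int]:
        return {k: v for k, v in vars(self).items()}


def _as_valid_values(values, minimum: int = 4) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64).ravel()
    if arr.size < minimum:
        raise ValidationError(f"need at least {minimum} values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("values must be finite")
    return arr


def estimate_background(values) -> float:
    """Background level: median of the outlier-trimmed low spectrum.

    The low spectrum is every value at or below Q1 of the full collection;
    within it, values below its own lower Tukey fence
    (Q1_low - 1.5 * IQR_low) are discarded as outliers (dead pixels, empty
    glass far darker than the tissue floor) before taking the median.
    """
    arr = _as_valid_values(values)
    q1 = float(np.quantile(arr, 0.25))
    low = arr[arr <= q1]
    q1_low, q3_low = np.quantile(low, [0.25, 0.75])
    fence = q1_low - 1.5 * (q3_low - q1_low)
    kept = low[low >= fence]
    if kept.size == 0:  # all low-spectrum values identical outliers; keep all
        kept = low
    return float(np.median(kept))


def subtract_background(image: MarkerImage, background: float) -> MarkerImage:
    """Subtract a scalar background from every pixel, floored at zero."""
    if background < 0:
        raise ValidationError("background must be >= 0")
    return image.with_pixels(np.maximum(image.pixels - background, 0.0))


def compute_threshold_stats(values, background: float = 0.0) -> ThresholdStats:
    """Robust statistics of a background-subtracted intensity collection.

    Quantiles use linear interpolation between order statistics (quantile p
    at rank p*(n-1)). The robust maximum is the largest value at or below
    the upper Tukey fence; if every value exceeds the fence (impossible with
    iqr >= 0, kept for safety) the plain maximum is used.
    """
    arr = _as_valid_values(values)
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lower_fence = q1 - 1.5 * iqr
    upper_fence = q3 + 1.5 * iqr
    inliers = arr[arr <= upper_fence]
    robust_max = float(inliers.max()) if inliers.size else float(arr.max())
    threshold = 0.5 * (robust_max + q3)
    return ThresholdStats(
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        mean=float(arr.mean()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        lower_fence=float(lower_fence),
        upper_fence=float(upper_fence),
        robust_max=robust_max,
        background=float(background),
        threshold=float(threshold),
        n_pixels=int(arr.size),
    )


def classify_positive(values: np.ndarray, stats: ThresholdStats) -> np.ndarray:
    """Boolean mask of positive pixels under the Q3-distance rule.

    A pixel is positive iff it is strictly closer to the robust maximum than
    to Q3: (robust_max - v) < (v - q3), equivalently v > (robust_max + q3)/2.
    Exact midpoints are negative. A degenerate image (robust_max == q3)
    returns the all-false mask with a warning.
    """
    values = np.asarray(values, dtype=np.float64)
    if stats.degenerate:
        logger.warning(
            "degenerate intensity distribution (robust_max == q3 == %.6g); "
            "no pixel classified positive",
            stats.q3,
        )
        return np.zeros(values.shape, dtype=bool)
    return values > stats.threshold


def count_positive(
    mask: np.ndarray,
    region_mask: np.ndarray,
    layer_mask: np.ndarray,
    region_label: int,
    layer_label: int | str,
) -> tuple[int, int]:
    """Positive and total pixel counts of one (region, layer) cell.

    ``layer_label`` is a layer integer or ``"whole"``, which matches any
    named tissue layer (layer mask > 0).
    """
    if not (mask.shape == region_mask.shape == layer_mask.shape):
        raise ValidationError(
            f"shape mismatch: mask {mask.shape}, region {region_mask.shape}, "
            f"layer {layer_mask.shape}"
        )
    sel = region_mask == region_label
    if layer_label == "whole":
        sel &= layer_mask > 0
    else:
        sel &= layer_mask == layer_label
    area = int(sel.sum())
    if area == 0:
        raise ZeroAreaError(
            f"(region={region_label}, layer={layer_label}) selects no pixels"
        )
    return int(mask[sel].sum()), area


def control_floor(control_image: MarkerImage) -> float:
    """Signal floor from a negative-control section (no primary antibody).

    Returns the 99th percentile of the control's background-subtracted
    intensities; used to raise the classification threshold so residual
    secondary-antibody/autofluorescence signal is never counted as fiber.
    """
    background = estimate_background(control_image.pixels)
    subtracted = subtract_background(control_image, background)
    return float(np.quantile(subtracted.pixels, 0.99))


def density_records(
    image: MarkerImage,
    labels: RegionLabelSet,
    sample_id: str,
    day: int,
    denoised: bool = False,
    control_floor_value: float | None = None,
    return_stats: bool = False,
):
    """Quantify one section into per-(region, layer) density records.

    ``image`` should already be denoised if denoising is wanted (the
    ``denoised`` flag is carried for the audit log only). Threshold
    statistics are computed once per image over all pixels inside any
    labeled region; one record is emitted per region present and per layer
    in (epidermis, dermis, whole), skipping zero-area cells (e.g. epidermis
    over an un-re-epithelialized wound bed).
    """
    if labels.shape != image.shape:
        raise ValidationError(
            f"label masks {labels.shape} do not match image {image.shape}"
        )
    scope = labels.region_mask != 0
    if scope.sum() < 4:
        raise ValidationError("labeled region contains fewer than 4 pixels")

    background = estimate_background(image.pixels[scope])
    subtracted = subtract_background(image, background)
    stats = compute_threshold_stats(subtracted.pixels[scope], background=background)
    if control_floor_value is not None and control_floor_value > stats.threshold:
        stats = replace(stats, threshold=float(control_floor_value))
    logger.info(
        "threshold stats for %s (day %d, denoised=%s): %s",
        sample_id,
        day,
        denoised,
        stats.as_dict(),
    )
    mask = classify_positive(subtracted.pixels, stats)

    layer_specs: list[tuple[str, int | str]] = [
        ("epidermis", 1),
        ("dermis", 2),
        ("whole", "whole"),
    ]
    records = []
    for region_label in labels.regions_present():
        region_name = labels.region_names[region_label]
        for layer_name, layer_sel in layer_specs:
            try:
                positives, area = count_positive(
                    mask, labels.region_mask, labels.layer_mask, region_label, layer_sel
                )
            except ZeroAreaError:
                continue
            records.append(
                DensityRecord(
                    sample_id=sample_id,
                    day=day,
                    region=region_name,
                    layer=layer_name,
                    positive_pixels=positives,
                    area_pixels=area,
                    density=positives / area,
                )
            )
    if return_stats:
        return records, stats
    return records
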