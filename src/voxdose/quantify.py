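"""Counts-to-activity calibration, dead-time bounds, and body contouring.

Quantitative SPECT needs a camera calibration factor (MBq per reconstructed
count), obtained from a phantom of known activity.  Count-rate losses are
bounded with the paralyzable detector model, m = n exp(-n tau); images are
not dead-time corrected here — the model only supports the error-bound
argument for omitting the correction.  Body contours come from a value
threshold with largest-connected-component cleanup; later low-count scans
are matched to an earlier reference contour by lowering the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .datamodel_io import ScalarVolume, ValidationError, VoiMask


@dataclass(frozen=True)
class CalibrationResult:
    factor_MBq_per_count: float
    source_activity_MBq: float
    total_counts: float

    def __post_init__(self):
        if self.total_counts <= 0 or self.source_activity_MBq <= 0:
            raise ValidationError("calibration needs positive activity and counts")
        expected = self.source_activity_MBq / self.total_counts
        if not math.isclose(self.factor_MBq_per_count, expected, rel_tol=1e-12):
            raise ValidationError("calibration factor inconsistent with activity/counts")


def calibrate(known_activity_MBq: float, counts_volume: ScalarVolume,
              voi: Optional[VoiMask] = None) -> CalibrationResult:
    """Calibration factor from a phantom of known (decay-corrected) activity.

    The caller supplies the activity already corrected to acquisition time.
    Counts are summed over ``voi`` when given, else over the whole volume.
    """
    if counts_volume.quantity != "counts":
        raise ValidationError("calibrate expects a counts volume")
    if not (known_activity_MBq > 0):
        raise ValidationError("known activity must be positive")
    total = float(counts_volume.values[voi.mask].sum()) if voi is not None \
        else counts_volume.total()
    if total <= 0:
        raise ValidationError("zero counts in the calibration volume")
    return CalibrationResult(factor_MBq_per_count=known_activity_MBq / total,
                             source_activity_MBq=known_activity_MBq,
                             total_counts=total)


def apply_calibration(counts_volume: ScalarVolume, factor: float) -> ScalarVolume:
    """Voxel-wise counts -> activity (MBq) conversion."""
    if counts_volume.quantity != "counts":
        raise ValidationError("apply_calibration expects a counts volume")
    if not (factor > 0):
        raise ValidationError("calibration factor must be positive")
    return ScalarVolume(counts_volume.grid, counts_volume.values * factor, "activity_MBq")


def deadtime_observed_rate(true_rate_cps: float, tau_s: float) -> float:
    """Paralyzable detector: observed rate m = n exp(-n tau)."""
    if true_rate_cps < 0 or tau_s < 0:
        raise ValidationError("rates and dead time must be non-negative")
    return true_rate_cps * math.exp(-true_rate_cps * tau_s)


def deadtime_loss_fraction(true_rate_cps: float, tau_s: float) -> float:
    """Fraction of true events lost, 1 - exp(-n tau)."""
    if true_rate_cps < 0 or tau_s < 0:
        raise ValidationError("rates and dead time must be non-negative")
    return 1.0 - math.exp(-true_rate_cps * tau_s)


_CONNECTIVITY_6 = ndimage.generate_binary_structure(3, 1)


def contour_by_threshold(volume: ScalarVolume, threshold: float) -> VoiMask:
    """Body mask: voxels above threshold, largest 6-connected component only."""
    if threshold < 0:
        raise ValidationError("threshold must be non-negative")
    raw = volume.values > threshold
    if not raw.any():
        raise ValidationError(f"threshold {threshold} leaves an empty mask; "
                              "reduce the threshold")
    labels, n = ndimage.label(raw, structure=_CONNECTIVITY_6)
    if n > 1:
        sizes = ndimage.sum_labels(raw, labels, index=np.arange(1, n + 1))
        raw = labels == (int(np.argmax(sizes)) + 1)
    return VoiMask(grid=volume.grid, mask=raw, label=f"body>{threshold:g}")


def match_contour(reference: VoiMask, volume: ScalarVolume,
                  n_iter: int = 60) -> tuple[float, VoiMask]:
    """Find the threshold whose contour best matches a reference contour.

    Bisection over the threshold: mask volume is non-increasing in the
    threshold, so the search brackets the reference voxel count and returns
    the threshold (and mask) minimising the absolute voxel-count mismatch.
    Intended for matching late, low-count scans to the first scan's body
    contour by lowering the threshold.
    """
    reference.require_nonempty()
    vmax = float(volume.values.max())
    if vmax <= 0:
        raise ValidationError("cannot match a contour on an all-zero volume")
    target = reference.n_voxels

    def count(th: float) -> int:
        try:
            return contour_by_threshold(volume, th).n_voxels
        except ValidationError:
            return 0

    lo, hi = 0.0, vmax
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if count(mid) >= target:
            lo = mid
        else:
            hi = mid
    best = min((lo, hi), key=lambda th: abs(count(th) - target))
    mask = contour_by_threshold(volume, best)
    if abs(mask.n_voxels - target) > max(1, 0.01 * target):
        import logging
        logging.getLogger("voxdose").warning(
            "contour match off by %d voxels (target %d); returning best found",
            mask.n_voxels - target, target)
    return best, mask
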