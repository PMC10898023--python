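"""Quantitative-CT bone-mass measurement and labeling.

Trabecular bone mineral density (BMD, mg/cm3) is measured in a region of
interest placed in the central cancellous bone of a vertebral body,
avoiding the cortical rim and the basivertebral vessel.  The per-subject
value ``bmd_individual`` is the mean of the L1 and L2 measurements (or
the single available one), and the three bone-mass classes follow the
standard QCT cut-offs:

* normal:        BMD > 120 mg/cm3
* osteopenia:    80 <= BMD <= 120 mg/cm3 (both bounds inclusive)
* osteoporosis:  BMD < 80 mg/cm3
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import MeasurementError, ValidationError

__all__ = ["LABELS", "OSTEOPENIA_LOW", "OSTEOPENIA_HIGH", "RoiSpec",
           "BmdResult", "classify_bmd", "subject_bmd", "measure_roi_bmd",
           "measure_subject"]

LABELS = ("normal", "osteopenia", "osteoporosis")
OSTEOPENIA_LOW = 80.0
OSTEOPENIA_HIGH = 120.0


def classify_bmd(bmd_individual: float) -> str:
    """Three-class bone-mass label from the per-subject BMD (mg/cm3)."""
    b = float(bmd_individual)
    if not math.isfinite(b) or b <= 0:
        raise ValidationError(f"BMD must be positive and finite, got {bmd_individual!r}")
    if b > OSTEOPENIA_HIGH:
        return "normal"
    if b >= OSTEOPENIA_LOW:
        return "osteopenia"
    return "osteoporosis"


def subject_bmd(bmd_l1: float | None, bmd_l2: float | None = None) -> float:
    """Per-subject BMD: mean of the available vertebral measurements."""
    vals = [float(v) for v in (bmd_l1, bmd_l2) if v is not None]
    if not vals:
        raise ValidationError("at least one vertebral BMD value is required")
    return float(np.mean(vals))


@dataclass(frozen=True)
class RoiSpec:
    """Deterministic surrogate for an operator-placed central cancellous ROI.

    The mask is eroded by ``erosion_margin`` pixels to stay clear of the
    cortical rim, then the fraction ``target_area_fraction`` of remaining
    pixels closest to the mask centroid forms the ROI.  With
    ``vessel_exclusion``, pixels more than 3 SD below the ROI median are
    dropped in a single pass (vessel voids are much darker than
    trabecular bone).
    """

    erosion_margin: int = 3
    vessel_exclusion: bool = True
    target_area_fraction: float = 0.6

    def __post_init__(self):
        if self.erosion_margin < 0:
            raise ValidationError("erosion_margin must be >= 0")
        if not (0.0 < self.target_area_fraction <= 1.0):
            raise ValidationError("target_area_fraction must be in (0, 1]")

    @classmethod
    def for_image_size(cls, image_size: int, **kw) -> "RoiSpec":
        """Default margin of 3 px at 512 px, scaled linearly (min 1 px)."""
        margin = max(1, round(3 * image_size / 512))
        return cls(erosion_margin=margin, **kw)


@dataclass(frozen=True)
class BmdResult:
    bmd_l1: float | None
    bmd_l2: float | None
    bmd_individual: float
    label: str
    roi_pixel_count: int


def measure_roi_bmd(slice_: np.ndarray, mask: np.ndarray, roi: RoiSpec,
                    calibration: tuple[float, float] = (1.0, 0.0)) -> tuple[float, int]:
    """Measure BMD (mg/cm3) in the central cancellous ROI of one slice.

    ``calibration`` is (slope, intercept) of the intensity = slope*BMD +
    intercept map; returns (bmd, roi_pixel_count).
    """
    slice_ = np.asarray(slice_, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if slice_.shape != mask.shape:
        raise MeasurementError(f"slice {slice_.shape} vs mask {mask.shape} shape mismatch")
    if roi.erosion_margin > 0:
        core = ndimage.binary_erosion(mask, iterations=roi.erosion_margin)
    else:
        core = mask
    if not core.any():
        raise MeasurementError(
            f"empty ROI: mask of {int(mask.sum())} px vanished after eroding "
            f"{roi.erosion_margin} px")
    ys, xs = np.nonzero(core)
    if roi.target_area_fraction < 1.0:
        cy, cx = ys.mean(), xs.mean()
        d2 = (ys - cy) ** 2 + (xs - cx) ** 2
        keep = max(1, int(round(roi.target_area_fraction * ys.size)))
        order = np.argsort(d2, kind="stable")[:keep]
        ys, xs = ys[order], xs[order]
    vals = slice_[ys, xs]
    if roi.vessel_exclusion and vals.size > 2:
        med = np.median(vals)
        sd = vals.std()
        if sd > 0:
            sel = vals >= med - 3.0 * sd
            vals = vals[sel]
    slope, intercept = calibration
    if slope == 0:
        raise MeasurementError("calibration slope must be nonzero")
    bmd = (float(vals.mean()) - intercept) / slope
    return bmd, int(vals.size)


def measure_subject(l1_slice, l1_mask, l2_slice=None, l2_mask=None,
                    roi: RoiSpec | None = None,
                    calibration: tuple[float, float] = (1.0, 0.0)) -> BmdResult:
    """Measure both vertebrae (L2 optional) and assemble the subject result."""
    if roi is None:
        roi = RoiSpec.for_image_size(np.asarray(l1_slice).shape[0])
    bmd_l1, n1 = measure_roi_bmd(l1_slice, l1_mask, roi, calibration)
    bmd_l2, n2 = (None, 0)
    if l2_slice is not None:
        if l2_mask is None:
            raise ValidationError("l2_slice given without l2_mask")
        bmd_l2, n2 = measure_roi_bmd(l2_slice, l2_mask, roi, calibration)
    bmd_ind = subject_bmd(bmd_l1, bmd_l2)
    return BmdResult(bmd_l1=bmd_l1, bmd_l2=bmd_l2, bmd_individual=bmd_ind,
                     label=classify_bmd(bmd_ind), roi_pixel_count=n1 + n2)
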