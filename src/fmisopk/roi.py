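"""ROI definition, TAC extraction and static hypoxia scoring.

Conventions: images are numpy arrays indexed (x, y, z[, frame]) with 0-based
voxel indices; masks share the image grid and physical spacing is metadata
only.  The tumor ROI for dynamic analysis is conventionally drawn on the
last frame (where trapped tracer dominates) and the left-ventricle blood ROI
on the first-minute frames (where the bolus dominates); both are produced by
fractional-maximum thresholding with largest-connected-component cleanup to
suppress necrotic regions and speckle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EmptyRoiError, GridError, InvalidBloodError, InvalidSpecError
from .kinetics import InputFunction
from .tac import FrameSchedule, TimeActivityCurve

__all__ = ["RegionMask", "RoiSummary", "threshold_roi", "extract_tac",
           "lv_input_function", "static_summary", "HYPOXIA_TB_CUTOFF"]

#: Tumor-to-blood activity ratio above which tissue is scored hypoxic.
HYPOXIA_TB_CUTOFF = 1.2

#: Default threshold as a fraction of the in-box maximum.
DEFAULT_THRESHOLD_FRACTION = 0.5


@dataclass(frozen=True)
class RegionMask:
    """Boolean 3D region on the image grid."""

    mask: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    label: str = ""

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        if mask.ndim != 3:
            raise InvalidSpecError("region mask must be 3D")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class RoiSummary:
    """Static-uptake summary with the T/B hypoxia call."""

    mean_uptake: float       # %ID/g
    blood_uptake: float      # %ID/g
    tb_ratio: float
    hypoxic: bool
    n_voxels: int = 0
    cutoff: float = HYPOXIA_TB_CUTOFF


def threshold_roi(volume: np.ndarray, seed_box: tuple[tuple[int, int], ...] | None = None,
                  frac: float = DEFAULT_THRESHOLD_FRACTION,
                  voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
                  label: str = "") -> RegionMask:
    """Segment the voxels >= ``frac`` of the maximum inside a bounding box.

    ``seed_box`` is ``((x0, x1), (y0, y1), (z0, z1))`` in half-open voxel
    indices (None = whole grid).  Only the largest 6-connected component is
    kept, which removes thresholding speckle.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise InvalidSpecError("expected a 3D volume")
    if not 0.0 < frac < 1.0:
        raise InvalidSpecError("threshold fraction must lie in (0, 1)")
    if seed_box is None:
        seed_box = tuple((0, n) for n in volume.shape)
    slices = []
    for (lo, hi), n in zip(seed_box, volume.shape):
        if not (0 <= lo < hi <= n):
            raise InvalidSpecError(f"seed box {seed_box} exceeds grid {volume.shape}")
        slices.append(slice(lo, hi))
    sub = volume[tuple(slices)]
    level = frac * float(sub.max())
    local = sub >= level
    if not local.any():
        raise EmptyRoiError("threshold produced an empty ROI")
    labels, n_comp = ndimage.label(local)
    if n_comp > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_comp + 1))
        local = labels == (1 + int(np.argmax(sizes)))
    mask = np.zeros(volume.shape, dtype=bool)
    mask[tuple(slices)] = local
    return RegionMask(mask=mask, voxel_size_mm=voxel_size_mm, label=label)


def extract_tac(image4d: np.ndarray, mask: RegionMask,
                schedule: FrameSchedule, unit: str = "Bq/mL") -> TimeActivityCurve:
    """Mean activity over the mask per frame -> a region TAC."""
    image4d = np.asarray(image4d, dtype=float)
    if image4d.ndim != 4:
        raise GridError("expected a 4D (x, y, z, frame) image")
    if image4d.shape[:3] != mask.mask.shape:
        raise GridError(
            f"image grid {image4d.shape[:3]} does not match mask {mask.mask.shape}"
        )
    if image4d.shape[3] != schedule.n_frames:
        raise GridError(
            f"image has {image4d.shape[3]} frames, schedule {schedule.n_frames}"
        )
    if mask.n_voxels == 0:
        raise EmptyRoiError("cannot extract a TAC from an empty mask")
    values = image4d[mask.mask].mean(axis=0)
    return TimeActivityCurve(schedule, values, unit=unit,
                             allow_negative=bool(np.any(values < 0)))


def lv_input_function(image4d: np.ndarray, schedule: FrameSchedule,
                      frac: float = DEFAULT_THRESHOLD_FRACTION,
                      seed_box: tuple[tuple[int, int], ...] | None = None,
                      ) -> tuple[InputFunction, RegionMask]:
    """Image-derived plasma input from an early-bolus (left-ventricle) ROI.

    The blood ROI is thresholded on the mean of the frames fully inside the
    first minute, when the vascular bolus is the hottest structure; its TAC,
    sampled at frame midpoints, is returned as C_p together with the mask.
    """
    image4d = np.asarray(image4d, dtype=float)
    if image4d.ndim != 4:
        raise GridError("expected a 4D (x, y, z, frame) image")
    early = (schedule.frame_start >= 0) & (schedule.frame_end <= 60.0 + 1e-9)
    if not np.any(early):
        raise InvalidSpecError("no frame lies fully inside the first minute")
    early_mean = image4d[..., early].mean(axis=3)
    mask = threshold_roi(early_mean, seed_box=seed_box, frac=frac, label="blood-pool")
    tac = extract_tac(image4d, mask, schedule)
    # samples at frame midpoints; hold the last value through the final
    # half-frame so the curve supports the full acquisition window
    times = np.concatenate([schedule.midpoints(), schedule.frame_end[-1:]])
    values = np.clip(np.concatenate([tac.values, tac.values[-1:]]), 0.0, None)
    cp = InputFunction(times, values)
    return cp, mask


def static_summary(tumor_mean: float, blood_mean: float,
                   cutoff: float = HYPOXIA_TB_CUTOFF, n_voxels: int = 0) -> RoiSummary:
    """Score static uptake via the tumor-to-blood ratio.

    T/B strictly greater than the cutoff (default 1.2) is called hypoxic; a
    ratio exactly at the cutoff is not.
    """
    if not blood_mean > 0:
        raise InvalidBloodError("blood mean uptake must be positive")
    tb = tumor_mean / blood_mean
    return RoiSummary(mean_uptake=float(tumor_mean), blood_uptake=float(blood_mean),
                      tb_ratio=float(tb), hypoxic=bool(tb > cutoff),
                      n_voxels=n_voxels, cutoff=cutoff)
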