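"""Voxelwise parametric maps of Ki (Patlak) and k3 (compartmental).

Ki mapping runs a Patlak regression per voxel over the whole body — cheap
because all voxels share the same normalized-time axis — and is typically
driven by either the plasma input or a muscle reference TAC.  k3 mapping
fits the irreversible compartment model per voxel, restricted to the tumor,
warm-started from the whole-ROI fit; it separates specific trapping from
delivery, which Ki mixes together.  Failed voxels are carried in a validity
mask with a NaN sentinel rather than aborting the map.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import FmisopkError, InvalidBackgroundError, InvalidSpecError
from .fitting import FitConfig, fit_tac
from .kinetics import FrameAveragedModel, InputFunction
from .patlak import DEFAULT_T_STAR_MIN, CP_FLOOR_FRACTION
from .roi import RegionMask, extract_tac
from .tac import FrameSchedule, TimeActivityCurve

__all__ = ["ParametricMap", "ki_map", "k3_map", "map_positive_fraction",
           "contrast_ratio", "DEFAULT_MAP_LEVEL_FRACTION"]

#: Default "map volume" threshold: fraction of the within-tumor map maximum.
DEFAULT_MAP_LEVEL_FRACTION = 0.2


@dataclass(frozen=True)
class ParametricMap:
    """3D map of one kinetic parameter with a validity mask.

    Invalid voxels hold NaN and are excluded from all statistics; valid
    values are nonnegative (negative Patlak slopes are clamped to zero).
    """

    values: np.ndarray
    valid: np.ndarray
    parameter: str           # "Ki" | "k3"
    units: str

    def __post_init__(self):
        if self.values.shape != self.valid.shape or self.values.ndim != 3:
            raise InvalidSpecError("map values and validity mask must be equal 3D grids")

    def masked_values(self, mask: RegionMask | None = None) -> np.ndarray:
        """Valid map values, optionally restricted to a region."""
        sel = self.valid if mask is None else (self.valid & mask.mask)
        return self.values[sel]


def _patlak_design(driver: InputFunction, schedule: FrameSchedule, t_star: float):
    """Shared per-voxel Patlak design: x-axis, selection and driver samples."""
    mid = schedule.midpoints()
    cp_mid = driver(mid)
    cum = np.concatenate([[0.0], np.cumsum(
        0.5 * np.diff(driver.sample_times)
        * (driver.plasma_concentration[:-1] + driver.plasma_concentration[1:]))])
    cum_mid = np.interp(mid, driver.sample_times, cum)
    floor = CP_FLOOR_FRACTION * float(driver.plasma_concentration.max())
    sel = (cp_mid > floor) & (mid >= t_star * 60.0)
    x = cum_mid[sel] / cp_mid[sel] / 60.0
    return x, sel, cp_mid[sel]


def ki_map(image4d: np.ndarray, driver: InputFunction | TimeActivityCurve,
           body_mask: RegionMask, schedule: FrameSchedule,
           t_star: float = DEFAULT_T_STAR_MIN) -> ParametricMap:
    """Voxelwise Patlak slope map over a body mask.

    ``driver`` is the plasma input function, or a reference-tissue TAC
    (then the slope is a Ki-like rate in 1/min).  Negative slopes are clamped
    to zero; voxels whose regression is undefined are marked invalid.
    """
    if isinstance(driver, TimeActivityCurve):
        driver = InputFunction(driver.schedule.midpoints(),
                               np.clip(driver.values, 0.0, None))
    if body_mask.n_voxels == 0:
        raise InvalidSpecError("body mask is empty")
    image4d = np.asarray(image4d, dtype=float)
    x, sel, cp_sel = _patlak_design(driver, schedule, t_star)
    shape = image4d.shape[:3]
    values = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    if x.size < 3:
        return ParametricMap(values, valid, "Ki", "mL/g/min")
    vox = image4d[body_mask.mask][:, sel]           # (n_voxels, n_points)
    y = vox / cp_sel                                # shared driver across voxels
    xc = x - x.mean()
    denom = float(np.sum(xc**2))
    slopes = (y - y.mean(axis=1, keepdims=True)) @ xc / denom
    ok = np.isfinite(slopes)
    slopes = np.where(ok, np.clip(slopes, 0.0, None), np.nan)
    values[body_mask.mask] = slopes
    valid[body_mask.mask] = ok
    return ParametricMap(values, valid, "Ki", "mL/g/min")


def k3_map(image4d: np.ndarray, cp: InputFunction, tumor_mask: RegionMask,
           schedule: FrameSchedule, cfg: FitConfig | None = None) -> ParametricMap:
    """Voxelwise k3 map from irreversible compartment fits inside the tumor.

    The whole-tumor ROI fit provides the initialization for every voxel fit
    (cuts non-convergence and wall time); voxel fits use a single start.
    Voxels that fail to fit — no signal, non-convergence — are invalid.
    """
    if tumor_mask.n_voxels == 0:
        raise InvalidSpecError("tumor mask is empty")
    cfg = cfg or FitConfig(model="irreversible")
    if cfg.model != "irreversible":
        raise InvalidSpecError("k3 mapping uses the irreversible model")
    image4d = np.asarray(image4d, dtype=float)
    engine = FrameAveragedModel(cp, schedule)
    roi_tac = extract_tac(image4d, tumor_mask, schedule)
    try:
        roi_fit = fit_tac(roi_tac, cp, cfg, model_engine=engine)
        p = roi_fit.params
        voxel_cfg = replace(cfg, init_K1=max(p.K1, 1e-4), init_k2=max(p.k2, 1e-4),
                            init_k3=max(p.k3, 1e-4), init_w_p=min(p.w_p, 0.9),
                            init_w_d=min(p.w_d, 1.0 - min(p.w_p, 0.9)),
                            n_starts=1, tolerance=max(cfg.tolerance, 1e-10))
    except FmisopkError:
        voxel_cfg = replace(cfg, n_starts=1, tolerance=max(cfg.tolerance, 1e-10))
    shape = image4d.shape[:3]
    values = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    idx = np.argwhere(tumor_mask.mask)
    series = image4d[tumor_mask.mask]
    for row, (i, j, k) in enumerate(idx):
        v = series[row]
        tac = TimeActivityCurve(schedule, v, allow_negative=bool(np.any(v < 0)))
        try:
            res = fit_tac(tac, cp, voxel_cfg, model_engine=engine)
        except FmisopkError:
            continue
        if res.converged:
            values[i, j, k] = res.params.k3
            valid[i, j, k] = True
    return ParametricMap(values, valid, "k3", "1/min")


def map_positive_fraction(pmap: ParametricMap, tumor_mask: RegionMask,
                          level: float) -> float:
    """Percent of tumor voxels where the map is valid and >= ``level``.

    This is the "map volume over tumor volume" overlap figure; it depends on
    the chosen level (a sensible default is 20% of the within-tumor maximum).
    """
    if tumor_mask.n_voxels == 0:
        raise InvalidSpecError("tumor mask is empty")
    hit = tumor_mask.mask & pmap.valid & (np.nan_to_num(pmap.values, nan=-np.inf) >= level)
    return 100.0 * float(hit.sum()) / float(tumor_mask.n_voxels)


def contrast_ratio(volume: np.ndarray, tumor_mask: RegionMask,
                   background_mask: RegionMask,
                   valid: np.ndarray | None = None) -> float:
    """Mean(tumor) / mean(background) over (optionally valid) voxels."""
    volume = np.asarray(volume, dtype=float)
    tsel = tumor_mask.mask if valid is None else (tumor_mask.mask & valid)
    bsel = background_mask.mask if valid is None else (background_mask.mask & valid)
    if not tsel.any() or not bsel.any():
        raise InvalidSpecError("tumor/background selections are empty")
    bg = float(volume[bsel].mean())
    if not bg > 0:
        raise InvalidBackgroundError("background mean must be positive")
    return float(volume[tsel].mean()) / bg
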