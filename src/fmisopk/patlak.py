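"""Gjedde-Patlak graphical analysis of irreversible tracer uptake.

For a tracer with an effectively irreversible compartment, plotting

    y(t) = C_t(t) / C_p(t)   against   x(t) = int_0^t C_p(s) ds / C_p(t)

becomes linear once the reversible pools have equilibrated (t >= t*); the
slope of the late-time line is the net influx constant Ki = K1*k3/(k2+k3)
(mL/g/min) and the intercept the effective distribution volume V0.  The
method needs no compartmental fit, which makes it cheap enough for
whole-body voxelwise mapping; a reference-tissue curve (typically muscle)
can replace C_p, yielding a relative slope in 1/min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyTransformError, InsufficientPointsError, InvalidSpecError
from .kinetics import InputFunction
from .tac import TimeActivityCurve

__all__ = ["PatlakPoints", "PatlakFit", "patlak_transform", "patlak_fit",
           "reference_patlak", "DEFAULT_T_STAR_MIN"]

#: Default linearity onset t*, minutes post injection.  Safely past the fast
#: exponentials implied by typical FMISO tumor rate constants.
DEFAULT_T_STAR_MIN = 30.0

#: Frames where C_p falls below this fraction of its peak are flagged invalid
#: (division stability).
CP_FLOOR_FRACTION = 0.01


@dataclass(frozen=True)
class PatlakPoints:
    """Patlak coordinates at frame midpoints with validity flags."""

    x: np.ndarray            # normalized time, minutes
    y: np.ndarray            # tissue-to-plasma ratio, unitless
    valid: np.ndarray        # bool per point
    t_min: np.ndarray        # frame midpoint, minutes post injection
    frame_index: np.ndarray


@dataclass(frozen=True)
class PatlakFit:
    """OLS line through the late Patlak points."""

    Ki: float                # slope, mL/g/min (1/min for a reference tissue)
    V0: float                # intercept, unitless
    n_points: int
    r_squared: float
    residual_std: float
    t_star_min: float


def patlak_transform(tissue_tac: TimeActivityCurve, cp: InputFunction) -> PatlakPoints:
    """Compute Patlak coordinates for a tissue TAC against a plasma input.

    x and y are evaluated at frame midpoints; the running integral of C_p is
    trapezoidal on the input sampling grid (exact for the piecewise-linear
    convention used throughout).
    """
    mid = tissue_tac.schedule.midpoints()
    if mid[-1] > cp.t_max + 1e-9:
        raise InvalidSpecError("TAC extends beyond the input-function support")
    cp_mid = cp(mid)
    cum = np.concatenate([[0.0], np.cumsum(
        0.5 * np.diff(cp.sample_times)
        * (cp.plasma_concentration[:-1] + cp.plasma_concentration[1:]))])
    cum_mid = np.interp(mid, cp.sample_times, cum)
    floor = CP_FLOOR_FRACTION * float(cp.plasma_concentration.max())
    valid = cp_mid > max(floor, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(valid, cum_mid / cp_mid, np.nan) / 60.0  # minutes
        y = np.where(valid, tissue_tac.values / cp_mid, np.nan)
    if not np.any(valid):
        raise EmptyTransformError("no valid Patlak points (C_p nonpositive throughout)")
    return PatlakPoints(x=x, y=y, valid=valid, t_min=mid / 60.0,
                        frame_index=np.arange(mid.size))


def patlak_fit(points: PatlakPoints, t_star: float = DEFAULT_T_STAR_MIN) -> PatlakFit:
    """Ordinary least-squares Patlak line over valid points with t >= t*.

    ``t_star`` is in minutes post injection (actual time, not normalized
    time).  Requires at least 3 usable points.
    """
    sel = points.valid & (points.t_min >= t_star)
    if np.count_nonzero(sel) < 3:
        raise InsufficientPointsError(
            f"need >= 3 valid Patlak points at t >= {t_star} min, "
            f"got {np.count_nonzero(sel)}"
        )
    x, y = points.x[sel], points.y[sel]
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PatlakFit(
        Ki=float(slope), V0=float(intercept), n_points=int(x.size),
        r_squared=r2, residual_std=float(np.sqrt(ss_res / max(x.size - 2, 1))),
        t_star_min=float(t_star),
    )


def reference_patlak(tissue_tac: TimeActivityCurve, reference_tac: TimeActivityCurve,
                     t_star: float = DEFAULT_T_STAR_MIN) -> PatlakFit:
    """Patlak analysis with a reference-tissue TAC replacing the plasma input.

    Used for whole-body Ki-like mapping when a plasma curve is unreliable;
    the reference (e.g. muscle) must remain strictly positive at late frames.
    The returned slope is relative to the reference and carries units 1/min.
    """
    mid = reference_tac.schedule.midpoints()
    late = mid >= t_star * 60.0
    if np.any(late) and not np.all(reference_tac.values[late] > 0):
        raise InvalidSpecError("reference TAC must be strictly positive at late frames")
    ref_input = InputFunction(mid, np.clip(reference_tac.values, 0.0, None))
    points = patlak_transform(tissue_tac, ref_input)
    return patlak_fit(points, t_star=t_star)
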