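"""Two-tissue compartment model for an irreversibly (or reversibly) trapped tracer.

The tissue is described by two serial compartments fed from arterial plasma:
a non-specific diffusive pool ``C_d`` and a specific accumulative pool
``C_a`` (for FMISO: nitroimidazole reduction products retained in viable
hypoxic cells)::

    dC_d/dt = K1*C_p - (k2 + k3)*C_d + k4*C_a
    dC_a/dt = k3*C_d - k4*C_a

with ``k4 = 0`` in the irreversible variant.  Transport is purely diffusive;
rate constants are conventionally quoted per minute (K1 in mL/g/min) while
the internal time axis is seconds, so rates are divided by 60 at evaluation.

The measured ROI signal is a convex mixture of the three concentrations::

    C_ROI(t) = w_p*C_p(t) + w_d*C_d(t) + w_a*C_a(t),   w_p + w_d + w_a = 1

where ``w_p`` is the fractional blood volume of the region.

Solution method
---------------
``C_p`` is treated as piecewise linear between its samples (ramped linearly
from (0, 0) before the first sample: the tracer is injected at acquisition
start).  The system is linear with constant coefficients, so both state
variables are exact linear combinations of exponential convolutions

    h_lambda(t) = int_0^t exp(lambda*(t-s)) * C_p(s) ds

with the (always real, nonpositive) eigenvalues of the rate matrix.  Each
convolution obeys an exact one-step recurrence per C_p segment, so results
are independent of any ODE step-size choice; on uniform grids the recurrence
is evaluated as a first-order IIR filter at C speed.  Frame averages are
obtained in closed form from h at the frame boundaries, matching how PET
frames integrate counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .errors import (
    ExtrapolationError,
    GridError,
    InvalidSpecError,
    UndefinedMacroError,
)
from .tac import FrameSchedule, TimeActivityCurve

__all__ = [
    "KineticParams",
    "InputFunction",
    "CompartmentCurves",
    "FrameAveragedModel",
    "solve_two_tissue",
    "roi_signal",
    "frame_average_signal",
    "macro_influx_rate",
]


@dataclass(frozen=True)
class KineticParams:
    """Micro-parameters of one tissue unit (ROI or voxel).

    Rates are per minute (K1 in mL/g/min); weights are fractions summing to 1.
    """

    K1: float
    k2: float
    k3: float
    k4: float = 0.0
    w_p: float = 0.05
    w_d: float = 0.60
    w_a: float = 0.35

    def __post_init__(self):
        for name in ("K1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be nonnegative")
        for name in ("w_p", "w_d", "w_a"):
            w = getattr(self, name)
            if not 0.0 <= w <= 1.0:
                raise InvalidSpecError(f"{name} must lie in [0, 1]")
        if abs(self.w_p + self.w_d + self.w_a - 1.0) > 1e-9:
            raise InvalidSpecError("w_p + w_d + w_a must equal 1")

    @property
    def weights(self) -> tuple[float, float, float]:
        return (self.w_p, self.w_d, self.w_a)


@dataclass(frozen=True)
class InputFunction:
    """Sampled plasma input function C_p(t), piecewise linear between samples.

    In practice an image-derived left-ventricle curve stands in for arterial
    plasma; no plasma/whole-blood or delay correction is applied.
    """

    sample_times: np.ndarray
    plasma_concentration: np.ndarray
    interpolation: str = "linear"

    def __post_init__(self):
        t = np.asarray(self.sample_times, dtype=float)
        c = np.asarray(self.plasma_concentration, dtype=float)
        if t.ndim != 1 or t.shape != c.shape or t.size == 0:
            raise InvalidSpecError("times/concentrations must be equal-length 1D arrays")
        if np.any(np.diff(t) <= 0):
            raise InvalidSpecError("sample times must be strictly increasing")
        if t[0] < 0:
            raise InvalidSpecError("sample times must be nonnegative")
        if not np.all(np.isfinite(c)):
            raise InvalidSpecError("plasma concentrations must be finite")
        if np.any(c < 0):
            raise InvalidSpecError("plasma concentrations must be nonnegative")
        if self.interpolation != "linear":
            raise InvalidSpecError("only linear interpolation is supported")
        # Ramp from (0, 0): injection coincides with acquisition start.
        if t[0] > 0:
            t = np.concatenate([[0.0], t])
            c = np.concatenate([[0.0], c])
        object.__setattr__(self, "sample_times", t)
        object.__setattr__(self, "plasma_concentration", c)

    @property
    def t_max(self) -> float:
        return float(self.sample_times[-1])

    def __call__(self, t) -> np.ndarray:
        """Evaluate C_p by linear interpolation; error beyond the last sample."""
        t = np.asarray(t, dtype=float)
        if np.any(t > self.t_max + 1e-9) or np.any(t < 0):
            raise ExtrapolationError(
                f"requested times outside input-function support [0, {self.t_max}] s"
            )
        return np.interp(t, self.sample_times, self.plasma_concentration)


@dataclass(frozen=True)
class CompartmentCurves:
    """Instantaneous compartment concentrations on a common time grid."""

    times: np.ndarray
    C_d: np.ndarray
    C_a: np.ndarray


def macro_influx_rate(params: KineticParams) -> float:
    """Net influx rate Ki = K1*k3/(k2 + k3) of the irreversibly trapped tracer.

    Ki (mL/g/min) is the late-time Patlak slope of the irreversible model; it
    mixes delivery (K1, k2) with specific trapping (k3).
    """
    denom = params.k2 + params.k3
    if denom == 0.0:
        raise UndefinedMacroError("Ki undefined: k2 + k3 == 0")
    return params.K1 * params.k3 / denom


def _phi1(z: np.ndarray) -> np.ndarray:
    """(e^z - 1)/z, stable near 0."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    small = np.abs(z) < 1e-5
    zs = z[small]
    out[small] = 1.0 + zs / 2.0 + zs * zs / 6.0
    zb = z[~small]
    out[~small] = np.expm1(zb) / zb
    return out


def _phi2(z: np.ndarray) -> np.ndarray:
    """(e^z - 1 - z)/z^2, stable near 0."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    small = np.abs(z) < 1e-4
    zs = z[small]
    out[small] = 0.5 + zs / 6.0 + zs * zs / 24.0
    zb = z[~small]
    out[~small] = (np.expm1(zb) - zb) / (zb * zb)
    return out


class FrameAveragedModel:
    """Precomputed evaluation engine for one (input function, timeline) pair.

    Fitting and voxelwise mapping evaluate the model thousands of times with
    the same C_p and frame schedule; everything that does not depend on the
    kinetic parameters (the refined grid, segment slopes, cumulative C_p
    integrals, frame boundary indices) is computed once here.
    """

    def __init__(self, cp: InputFunction, schedule: FrameSchedule | None = None,
                 extra_times: np.ndarray | None = None):
        self.cp = cp
        self.schedule = schedule
        knots = [cp.sample_times]
        if schedule is not None:
            if schedule.frame_end[-1] > cp.t_max + 1e-9:
                raise ExtrapolationError(
                    "frame schedule extends beyond input-function support"
                )
            knots += [schedule.frame_start, schedule.frame_end[-1:]]
        if extra_times is not None:
            extra = np.asarray(extra_times, dtype=float)
            if extra.size and (extra.max() > cp.t_max + 1e-9 or extra.min() < 0):
                raise ExtrapolationError(
                    "evaluation times outside input-function support"
                )
            knots.append(extra)
        grid = np.unique(np.concatenate(knots))
        self.grid = grid
        self.cp_on_grid = np.interp(grid, cp.sample_times, cp.plasma_concentration)
        dt = np.diff(grid)
        self._dt = dt
        self._c0 = self.cp_on_grid[:-1]
        self._m = np.diff(self.cp_on_grid) / dt
        # P = cumulative integral of C_p (exact for piecewise-linear C_p),
        # Q = cumulative integral of P (C_p linear => P piecewise quadratic).
        seg_p = dt * (self._c0 + 0.5 * self._m * dt)
        self.P = np.concatenate([[0.0], np.cumsum(seg_p)])
        seg_q = self.P[:-1] * dt + 0.5 * self._c0 * dt**2 + self._m * dt**3 / 6.0
        self.Q = np.concatenate([[0.0], np.cumsum(seg_q)])
        self._uniform = bool(dt.size) and np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12)
        if schedule is not None:
            self._i_start = np.searchsorted(grid, schedule.frame_start)
            self._i_end = np.searchsorted(grid, schedule.frame_end)

    # -- exponential convolution ------------------------------------------

    def exp_conv(self, lam: float) -> np.ndarray:
        """h_lam(t) = int_0^t e^{lam (t-s)} C_p(s) ds on the grid (lam per second)."""
        if lam == 0.0:
            return self.P
        z = lam * self._dt
        g = self._dt * (self._c0 * _phi1(z) + self._m * self._dt * _phi2(z))
        if self._uniform:
            a = float(np.exp(z[0]))
            h = lfilter([1.0], [1.0, -a], g)
        else:
            e = np.exp(z)
            h = np.empty_like(g)
            acc = 0.0
            for j in range(g.size):
                acc = e[j] * acc + g[j]
                h[j] = acc
        return np.concatenate([[0.0], h])

    def _int_h(self, lam: float, h: np.ndarray) -> np.ndarray:
        """Cumulative integral of h_lam, from h' = lam*h + C_p (exact)."""
        if lam == 0.0:
            return self.Q
        return (h - self.P) / lam

    # -- eigen-structure ---------------------------------------------------

    @staticmethod
    def _eigen(params: KineticParams):
        """Eigen-decomposition of the per-second rate matrix applied to e1.

        Returns (lam1, lam2, beta1, beta2, gam1, gam2) such that
        C_d = K1s*(beta1*h1 + beta2*h2), C_a = K1s*(gam1*h1 + gam2*h2),
        with K1s = K1/60 and h_i = exp_conv(lam_i).
        """
        alpha = (params.k2 + params.k3) / 60.0
        k3s = params.k3 / 60.0
        k4s = params.k4 / 60.0
        disc = (alpha - k4s) ** 2 + 4.0 * k3s * k4s  # always >= 0: real spectrum
        root = np.sqrt(disc)
        lam1 = 0.5 * (-(alpha + k4s) + root)
        lam2 = 0.5 * (-(alpha + k4s) - root)
        if lam1 - lam2 < 1e-9 * max(alpha + k4s, 1e-30):
            # near-defective pair (k3*k4 ~ 0 and alpha ~ k4): split it slightly
            bump = max(1e-9 * max(alpha, k4s, 1e-12), 1e-15)
            lam1 += 0.5 * bump
            lam2 -= 0.5 * bump
        dl = lam1 - lam2
        beta1 = (-alpha - lam2) / dl
        beta2 = (alpha + lam1) / dl
        gam1 = k3s / dl
        gam2 = -k3s / dl
        return lam1, lam2, beta1, beta2, gam1, gam2

    # -- public evaluations ------------------------------------------------

    def curves(self, params: KineticParams) -> CompartmentCurves:
        """Instantaneous C_d, C_a at every grid point."""
        K1s = params.K1 / 60.0
        if K1s == 0.0:
            z = np.zeros_like(self.grid)
            return CompartmentCurves(self.grid, z, z.copy())
        lam1, lam2, b1, b2, g1, g2 = self._eigen(params)
        h1 = self.exp_conv(lam1)
        h2 = self.exp_conv(lam2)
        C_d = K1s * (b1 * h1 + b2 * h2)
        C_a = K1s * (g1 * h1 + g2 * h2)
        # clip tiny negative round-off; true solutions are nonnegative
        np.clip(C_d, 0.0, None, out=C_d)
        np.clip(C_a, 0.0, None, out=C_a)
        return CompartmentCurves(self.grid, C_d, C_a)

    def frame_average_components(self, params: KineticParams
                                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Frame-averaged (C_p, C_d, C_a) per frame, before weighting.

        The unweighted sum ``C_d + C_a`` is the total tissue concentration —
        the curve classical Patlak analysis is defined on.
        """
        if self.schedule is None:
            raise GridError("model was built without a frame schedule")
        i0, i1 = self._i_start, self._i_end
        dur = self.schedule.durations
        avg_cp = (self.P[i1] - self.P[i0]) / dur
        K1s = params.K1 / 60.0
        if K1s == 0.0:
            zero = np.zeros_like(avg_cp)
            return avg_cp, zero, zero.copy()
        lam1, lam2, b1, b2, g1, g2 = self._eigen(params)
        h1 = self.exp_conv(lam1)
        h2 = self.exp_conv(lam2)
        H1 = self._int_h(lam1, h1)
        H2 = self._int_h(lam2, h2)
        int_h1 = H1[i1] - H1[i0]
        int_h2 = H2[i1] - H2[i0]
        avg_cd = K1s * (b1 * int_h1 + b2 * int_h2) / dur
        avg_ca = K1s * (g1 * int_h1 + g2 * int_h2) / dur
        np.clip(avg_cd, 0.0, None, out=avg_cd)
        np.clip(avg_ca, 0.0, None, out=avg_ca)
        return avg_cp, avg_cd, avg_ca

    def frame_averages(self, params: KineticParams) -> np.ndarray:
        """Frame-averaged C_ROI per frame (the model prediction for a TAC)."""
        avg_cp, avg_cd, avg_ca = self.frame_average_components(params)
        return params.w_p * avg_cp + params.w_d * avg_cd + params.w_a * avg_ca


def solve_two_tissue(params: KineticParams, cp: InputFunction,
                     eval_times: np.ndarray) -> CompartmentCurves:
    """Solve the two-tissue system for C_d(t), C_a(t) at the requested times.

    Exact for piecewise-linear C_p (no step-size parameter); requesting times
    beyond the input-function support raises :class:`ExtrapolationError`.
    """
    eval_times = np.atleast_1d(np.asarray(eval_times, dtype=float))
    model = FrameAveragedModel(cp, schedule=None, extra_times=eval_times)
    full = model.curves(params)
    idx = np.searchsorted(model.grid, eval_times)
    return CompartmentCurves(eval_times, full.C_d[idx], full.C_a[idx])


def roi_signal(params: KineticParams, cp: InputFunction,
               curves: CompartmentCurves) -> np.ndarray:
    """Instantaneous ROI signal C_ROI = w_p*C_p + w_d*C_d + w_a*C_a."""
    if curves.C_d.shape != curves.times.shape or curves.C_a.shape != curves.times.shape:
        raise GridError("compartment curves and time grid have mismatched shapes")
    return (params.w_p * cp(curves.times)
            + params.w_d * curves.C_d
            + params.w_a * curves.C_a)


def frame_average_signal(params: KineticParams, cp: InputFunction,
                         schedule: FrameSchedule) -> TimeActivityCurve:
    """Frame-averaged model TAC on a schedule (what a PET scan would measure).

    ``value[i] = (1/dt_i) * int_{start_i}^{end_i} C_ROI(t) dt``, evaluated with
    the same per-segment closed form as the instantaneous solution.
    """
    model = FrameAveragedModel(cp, schedule=schedule)
    return TimeActivityCurve(schedule, model.frame_averages(params), unit="Bq/mL")
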