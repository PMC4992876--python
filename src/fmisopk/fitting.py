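"""Nonlinear least-squares estimation of two-tissue kinetic parameters.

A measured tumor TAC and a plasma input function are fitted with the
frame-averaged ROI model by bounded trust-region least squares
(``scipy.optimize.least_squares``).  Free parameters are K1, k2, k3 (and k4
for the reversible variant) plus the fractional blood volume w_p; by default
the extravascular volume 1 - w_p is divided between the diffusive and
accumulative pools at a fixed ratio (see Identifiability below), while
``weight_mode = "free"`` additionally frees w_d with the accumulative
fraction eliminated through the sum-to-one constraint
``w_a = 1 - w_p - w_d`` (internally ``w_d = (1 - w_p) * theta`` so box
bounds alone keep all three weights in [0, 1]).

Goodness of fit is the residual percentage

    epsilon = 100 * mean_i |tac_i - model_i| / max_i tac_i

a scale-free summary robust to near-zero early frames; a fit with
epsilon < 5% is conventionally accepted.  An alternative pointwise-relative
variant (restricted to frames above 10% of the TAC maximum) is available via
``FitConfig.epsilon_mode = "relative"``.

Identifiability
---------------
With *both* volume fractions free the weighted model is structurally
unidentifiable: for the irreversible variant the signal determines only
``w_p``, the pool decay rate ``k2 + k3`` and two amplitude combinations
(``K1*w_d - K1*w_a*k3/(k2+k3)`` and ``K1*w_a*k3/(k2+k3)``) — four
observables for five parameters, so a one-parameter family of rate/weight
combinations reproduces any noiseless TAC exactly and a fitted rate vector
depends on the initialization.  The default ``weight_mode = "fixed-split"``
therefore fixes the diffusive share of the extravascular volume at a
conventional value and fits only K1, k2, k3, (k4) and w_p, which is exactly
identifiable; ``weight_mode = "free"`` retains the fully free weights for
compatibility with the historical procedure, with the caveat above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import GridError, InvalidSpecError, UndefinedEpsilonError, UnfittableSignalError
from .kinetics import FrameAveragedModel, InputFunction, KineticParams
from .tac import TimeActivityCurve

__all__ = ["FitConfig", "FitResult", "ModelComparison", "fit_tac", "fit_error",
           "compare_models"]

#: Conventional acceptance threshold for the residual percentage, in %.
EPSILON_ACCEPT = 5.0


@dataclass(frozen=True)
class FitConfig:
    """Configuration of one kinetic fit.

    Defaults follow the conventional single initialization K1 = k2 = k3 =
    0.01, w_p = w_d = 0.1, with box bounds [0, 1] on every rate (per minute;
    K1 in mL/g/min) and weight.  ``n_starts`` additional jittered
    initializations (seeded, deterministic) are tried when the first attempt
    fails to converge or leaves epsilon above the acceptance threshold.
    """

    model: str = "irreversible"           # "irreversible" | "reversible"
    weight_mode: str = "fixed-split"      # "fixed-split" | "free"
    diffusive_split: float = 0.60 / 0.95  # w_d/(w_d+w_a) under fixed-split
    init_K1: float = 0.01
    init_k2: float = 0.01
    init_k3: float = 0.01
    init_k4: float = 0.01
    init_w_p: float = 0.1
    init_w_d: float = 0.1
    rate_bounds: tuple[float, float] = (0.0, 1.0)
    max_nfev: int = 2000
    tolerance: float = 1e-12              # ftol/xtol/gtol for the optimizer
    weighting: str = "uniform"            # "uniform" | "duration"
    epsilon_mode: str = "max_norm"        # "max_norm" | "relative"
    n_starts: int = 5
    multistart_seed: int = 20160822
    min_signal_ratio: float = 3.0         # refuse TACs below this multiple of background
    check_background: bool = True

    def __post_init__(self):
        if self.model not in ("irreversible", "reversible"):
            raise InvalidSpecError(f"unknown model variant {self.model!r}")
        if self.weight_mode not in ("fixed-split", "free"):
            raise InvalidSpecError(f"unknown weight mode {self.weight_mode!r}")
        if not 0.0 < self.diffusive_split < 1.0:
            raise InvalidSpecError("diffusive split must lie strictly in (0, 1)")
        if self.weighting not in ("uniform", "duration"):
            raise InvalidSpecError(f"unknown weighting {self.weighting!r}")
        if self.epsilon_mode not in ("max_norm", "relative"):
            raise InvalidSpecError(f"unknown epsilon mode {self.epsilon_mode!r}")
        if not self.tolerance > 0:
            raise InvalidSpecError("tolerance must be positive")
        lo, hi = self.rate_bounds
        for v in (self.init_K1, self.init_k2, self.init_k3, self.init_k4):
            if not lo <= v <= hi:
                raise InvalidSpecError("rate initials must lie within bounds")
        if not (0 <= self.init_w_p <= 1 and 0 <= self.init_w_d <= 1
                and self.init_w_p + self.init_w_d <= 1):
            raise InvalidSpecError("weight initials must be admissible fractions")


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters with goodness of fit and convergence metadata."""

    params: KineticParams
    epsilon: float
    converged: bool
    n_iter: int
    residuals: np.ndarray
    model_tac: TimeActivityCurve
    sse: float
    n_starts_used: int = 1

    @property
    def accepted(self) -> bool:
        """Whether epsilon meets the conventional < 5% residual criterion."""
        return self.epsilon < EPSILON_ACCEPT


@dataclass(frozen=True)
class ModelComparison:
    """Paired irreversible/reversible fits of one TAC."""

    irreversible: FitResult
    reversible: FitResult

    @property
    def epsilon_table(self) -> dict[str, float]:
        return {"irreversible": self.irreversible.epsilon,
                "reversible": self.reversible.epsilon}

    @property
    def fitted_k4(self) -> float:
        return self.reversible.params.k4


def fit_error(tac: TimeActivityCurve, model_tac: TimeActivityCurve,
              mode: str = "max_norm") -> float:
    """Residual percentage epsilon between a measured and a model TAC."""
    if tac.values.shape != model_tac.values.shape:
        raise GridError("TACs must have equal length")
    peak = float(np.max(tac.values))
    if peak <= 0:
        raise UndefinedEpsilonError("epsilon undefined for an all-nonpositive TAC")
    resid = np.abs(tac.values - model_tac.values)
    if mode == "max_norm":
        return float(100.0 * resid.mean() / peak)
    if mode == "relative":
        keep = tac.values >= 0.1 * peak
        return float(100.0 * np.mean(resid[keep] / tac.values[keep]))
    raise InvalidSpecError(f"unknown epsilon mode {mode!r}")


def _background_level(values: np.ndarray) -> float:
    """Robust per-frame noise scale used to refuse background-only TACs.

    Estimated from second differences (which annihilate any locally linear
    signal trend): sigma ~ 1.4826 * MAD(diff2) / sqrt(6).  Zero for noiseless
    curves, ~ the frame noise SD for pure background, so "TAC maximum below
    min_signal_ratio * background" identifies curves indistinguishable from
    noise without penalizing genuine early-peaking uptake.
    """
    if values.size < 4:
        return 0.0
    d2 = np.diff(values, n=2)
    return float(1.4826 * np.median(np.abs(d2 - np.median(d2))) / np.sqrt(6.0))


def _unpack(x: np.ndarray, cfg: FitConfig) -> KineticParams:
    """Map an optimizer vector to admissible KineticParams.

    fixed-split: [K1, k2, k3, (k4), w_p]; the extravascular volume 1 - w_p
    is split w_d : w_a = split : (1 - split).
    free: [K1, k2, k3, (k4), w_p, theta] with w_d = (1 - w_p)*theta, so box
    bounds alone keep all three weights in [0, 1].
    """
    rev = cfg.model == "reversible"
    K1, k2, k3 = x[0], x[1], x[2]
    k4 = x[3] if rev else 0.0
    rest = x[4:] if rev else x[3:]
    if cfg.weight_mode == "fixed-split":
        w_p = rest[0]
        theta = cfg.diffusive_split
    else:
        w_p, theta = rest
    w_d = (1.0 - w_p) * theta
    w_a = max(1.0 - w_p - w_d, 0.0)
    return KineticParams(K1=K1, k2=k2, k3=k3, k4=k4, w_p=w_p, w_d=w_d, w_a=w_a)


def _initial_vector(cfg: FitConfig) -> np.ndarray:
    rates = [cfg.init_K1, cfg.init_k2, cfg.init_k3]
    if cfg.model == "reversible":
        rates.append(cfg.init_k4)
    if cfg.weight_mode == "fixed-split":
        return np.array(rates + [cfg.init_w_p])
    theta0 = cfg.init_w_d / (1.0 - cfg.init_w_p) if cfg.init_w_p < 1.0 else 0.0
    return np.array(rates + [cfg.init_w_p, theta0])


def fit_tac(tac: TimeActivityCurve, cp: InputFunction, cfg: FitConfig | None = None,
            model_engine: FrameAveragedModel | None = None) -> FitResult:
    """Fit a two-tissue model to a measured TAC.

    Raises :class:`UnfittableSignalError` for TACs indistinguishable from
    background (mirroring the convention of reporting zero rates for tumors
    with no visible uptake rather than noise-fitted values); non-convergence
    is reported through ``FitResult.converged``, not an exception.

    ``model_engine`` lets voxelwise callers reuse one precomputed
    :class:`FrameAveragedModel` across many fits.
    """
    cfg = cfg or FitConfig()
    values = tac.values
    if not np.any(values > 0):
        raise UnfittableSignalError("TAC carries no positive signal")
    if np.count_nonzero(values) < 8:
        raise UnfittableSignalError("need at least 8 frames with nonzero signal")
    if cfg.check_background:
        bg = _background_level(values)
        if bg > 0 and float(values.max()) < cfg.min_signal_ratio * bg:
            raise UnfittableSignalError(
                "TAC maximum below the background-multiple threshold; "
                "treat rates as 0 rather than fitting noise"
            )
    engine = model_engine or FrameAveragedModel(cp, tac.schedule)
    if cfg.weighting == "duration":
        w = np.sqrt(tac.schedule.durations / tac.schedule.durations.mean())
    else:
        w = np.ones_like(values)

    def residual(x):
        return w * (engine.frame_averages(_unpack(x, cfg)) - values)

    n_rates = 4 if cfg.model == "reversible" else 3
    n_weights = 1 if cfg.weight_mode == "fixed-split" else 2
    nx = n_rates + n_weights
    lo = np.full(nx, cfg.rate_bounds[0])
    hi = np.full(nx, cfg.rate_bounds[1])
    lo[n_rates:], hi[n_rates:] = 0.0, 1.0  # weight coordinates always in [0, 1]

    def solve(x0):
        return least_squares(residual, x0, bounds=(lo, hi), method="trf",
                             ftol=cfg.tolerance, xtol=cfg.tolerance,
                             gtol=cfg.tolerance, max_nfev=cfg.max_nfev,
                             x_scale="jac")

    x0 = np.clip(_initial_vector(cfg), lo, hi)
    best = solve(x0)
    starts_used = 1
    params = _unpack(best.x, cfg)
    model_values = engine.frame_averages(params)
    eps = fit_error(tac, tac.with_values(model_values), mode=cfg.epsilon_mode)
    if (not best.success or eps >= EPSILON_ACCEPT) and cfg.n_starts > 1:
        rng = np.random.default_rng(cfg.multistart_seed)
        for _ in range(cfg.n_starts - 1):
            jitter = rng.lognormal(mean=0.0, sigma=1.0, size=nx)
            trial_x0 = np.clip(x0 * jitter, lo, hi)
            trial = solve(trial_x0)
            starts_used += 1
            if trial.success and trial.cost < best.cost:
                best = trial
        params = _unpack(best.x, cfg)
        model_values = engine.frame_averages(params)
        eps = fit_error(tac, tac.with_values(model_values), mode=cfg.epsilon_mode)
    return FitResult(
        params=params,
        epsilon=eps,
        converged=bool(best.success),
        n_iter=int(best.nfev),
        residuals=values - model_values,
        model_tac=tac.with_values(model_values),
        sse=float(2.0 * best.cost),
        n_starts_used=starts_used,
    )


def compare_models(tac: TimeActivityCurve, cp: InputFunction,
                   cfg_irrev: FitConfig | None = None,
                   cfg_rev: FitConfig | None = None) -> ModelComparison:
    """Fit both model variants to the same TAC and report paired results.

    For an irreversibly trapped tracer the reversible fit typically collapses
    onto the irreversible one with k4 of order 1e-4 per minute or below.
    """
    cfg_irrev = cfg_irrev or FitConfig(model="irreversible")
    cfg_rev = cfg_rev or FitConfig(model="reversible")
    if cfg_irrev.model != "irreversible" or cfg_rev.model != "reversible":
        raise InvalidSpecError("configs must be (irreversible, reversible) in order")
    engine = FrameAveragedModel(cp, tac.schedule)
    fit_i = fit_tac(tac, cp, cfg_irrev, model_engine=engine)
    fit_r = fit_tac(tac, cp, cfg_rev, model_engine=engine)
    return ModelComparison(irreversible=fit_i, reversible=fit_r)
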