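"""Synthetic input functions, TACs and 4D digital phantoms.

The generator emulates a 2 h, 52-frame small-animal dynamic FMISO
acquisition: a bolus-shaped plasma input function, region TACs produced by
the forward two-tissue model, and a voxelized phantom (blood pool, muscle
body, tumor with a normoxic rim and a hypoxic core) with frame-integrated
counting noise.  It provides ground-truth masks and parameter maps so that
every analysis stage can be validated round-trip without scan data.

Noise model: zero-mean Gaussian per frame with standard deviation
``sigma0 * sqrt(value / frame_duration)`` — the variance scales with
activity and inversely with frame duration, the standard surrogate for
reconstructed-PET counting noise (true Poisson sinogram simulation is out of
scope).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidSpecError
from .kinetics import FrameAveragedModel, InputFunction, KineticParams, macro_influx_rate
from .roi import RegionMask
from .tac import FrameSchedule, TimeActivityCurve, build_frame_schedule

__all__ = ["InputFunctionSpec", "PhantomSpec", "PhantomResult", "PRESETS", "NOISE_LEVELS",
           "preset_params", "default_schedule", "make_input_function",
           "simulate_tac", "simulate_dynamic_pet", "tissue_concentration_tac"]

#: Conventional 2 h dynamic acquisition: 52 contiguous frames.
DEFAULT_FRAME_BLOCKS = [(10, 30.0), (10, 60.0), (10, 120.0), (10, 150.0), (12, 300.0)]

#: Named noise levels (sigma0 of the counting-noise model), anchored to the
#: default input-function scale (peak 1000 Bq/mL, late tissue activity a few
#: hundred Bq/mL).  "low" ~ whole-tumor-ROI TACs (<1% relative SD in late
#: 300 s frames), "moderate" ~ small-ROI TACs (~2% late, ~15% in the first
#: 30 s frames), "high" ~ single-voxel TACs (~5% late, ~40% early).
NOISE_LEVELS = {"low": 2.0, "moderate": 5.0, "high": 15.0}

#: Default weights for tissue presets (fractional blood volume 5%; the
#: remaining tumor volume split 60/35 between diffusive and accumulative).
_PRESET_WEIGHTS = dict(w_p=0.05, w_d=0.60, w_a=0.35)

#: Tissue-preset rate constants (per minute; K1 in mL/g/min) for the two
#: xenograft scenarios at each imaging time point relative to therapy.
PRESETS: dict[str, KineticParams] = {
    "U87MG-1h": KineticParams(K1=0.1095, k2=0.0602, k3=0.0109, **_PRESET_WEIGHTS),
    "U87MG-6h": KineticParams(K1=0.1241, k2=0.0535, k3=0.0085, **_PRESET_WEIGHTS),
    "U87MG-24h": KineticParams(K1=0.0763, k2=0.0485, k3=0.0098, **_PRESET_WEIGHTS),
    "MDA-pre": KineticParams(K1=0.0115, k2=0.00123, k3=0.00149, **_PRESET_WEIGHTS),
    "MDA-1h": KineticParams(K1=0.0255, k2=0.00286, k3=0.03314, **_PRESET_WEIGHTS),
    "MDA-6h": KineticParams(K1=0.0264, k2=0.00259, k3=0.01678, **_PRESET_WEIGHTS),
    "MDA-24h": KineticParams(K1=0.0282, k2=0.00195, k3=0.00156, **_PRESET_WEIGHTS),
}


def preset_params(name: str) -> KineticParams:
    """Look up a named tissue preset (e.g. ``"MDA-1h"``, ``"U87MG-1h"``)."""
    try:
        return PRESETS[name]
    except KeyError:
        raise InvalidSpecError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def default_schedule() -> FrameSchedule:
    """The 52-frame, 2 h acquisition timeline."""
    return build_frame_schedule(DEFAULT_FRAME_BLOCKS)


@dataclass(frozen=True)
class InputFunctionSpec:
    """Bolus-shaped plasma curve: linear rise to a peak, tri-exponential washout.

    ``C_p(t) = peak_value * t/peak_time``                      for t <= peak_time
    ``C_p(t) = peak_value * sum_j w_j exp(-lambda_j (t-tp))``  afterwards,

    with ``w_j = A_j / sum(A)`` so the curve is continuous at the peak.  The
    decay constants (1/min) must be strictly ordered lambda1 > lambda2 >
    lambda3; a small lambda3 gives the slow late plateau characteristic of a
    long-circulating tracer.
    """

    peak_time_s: float = 30.0
    peak_value: float = 1000.0        # Bq/mL (arbitrary scale; model is linear)
    lambdas_per_min: tuple[float, float, float] = (3.0, 0.25, 0.003)
    amplitudes: tuple[float, float, float] = (0.6, 0.25, 0.15)
    duration_s: float = 7200.0
    sampling_s: float = 1.0

    def __post_init__(self):
        if not (self.peak_time_s > 0 and self.peak_value > 0):
            raise InvalidSpecError("peak time and value must be positive")
        l1, l2, l3 = self.lambdas_per_min
        if not (l1 > l2 > l3 > 0):
            raise InvalidSpecError("decay constants must satisfy lambda1 > lambda2 > lambda3 > 0")
        if any(a < 0 for a in self.amplitudes) or sum(self.amplitudes) <= 0:
            raise InvalidSpecError("amplitudes must be nonnegative with positive sum")
        if not self.duration_s > self.peak_time_s:
            raise InvalidSpecError("duration must exceed the peak time")
        if not self.sampling_s > 0:
            raise InvalidSpecError("sampling step must be positive")

    def analytic_integral(self) -> float:
        """Closed-form integral of C_p over [0, duration] (Bq*s/mL)."""
        w = np.asarray(self.amplitudes, float)
        w = w / w.sum()
        lam = np.asarray(self.lambdas_per_min, float) / 60.0   # 1/s
        rise = 0.5 * self.peak_value * self.peak_time_s
        tail_t = self.duration_s - self.peak_time_s
        tail = self.peak_value * np.sum(w / lam * (1.0 - np.exp(-lam * tail_t)))
        return float(rise + tail)


def make_input_function(spec: InputFunctionSpec | None = None) -> InputFunction:
    """Sample the bolus model on a regular grid -> an :class:`InputFunction`."""
    spec = spec or InputFunctionSpec()
    t = np.arange(0.0, spec.duration_s + 0.5 * spec.sampling_s, spec.sampling_s)
    w = np.asarray(spec.amplitudes, float)
    w = w / w.sum()
    lam = np.asarray(spec.lambdas_per_min, float) / 60.0
    tail = spec.peak_value * (w * np.exp(-lam * (t[:, None] - spec.peak_time_s))).sum(axis=1)
    values = np.where(t <= spec.peak_time_s, spec.peak_value * t / spec.peak_time_s, tail)
    return InputFunction(t, values)


def _noise_sd(values: np.ndarray, durations: np.ndarray, sigma0: float) -> np.ndarray:
    return sigma0 * np.sqrt(np.clip(values, 0.0, None) / durations)


def simulate_tac(params: KineticParams, cp: InputFunction, schedule: FrameSchedule,
                 noise_sigma0: float = 0.0, seed: int | None = None,
                 n_rep: int = 1) -> list[TimeActivityCurve]:
    """Noiseless-model frame averages plus frame-integrated counting noise.

    Returns ``n_rep`` independent replicate TACs (a list even for one);
    ``noise_sigma0 = 0`` reproduces the exact model frame averages.  Output
    is bit-reproducible for a given seed.
    """
    if noise_sigma0 < 0:
        raise InvalidSpecError("noise level must be nonnegative")
    if n_rep < 1:
        raise InvalidSpecError("n_rep must be >= 1")
    engine = FrameAveragedModel(cp, schedule)
    clean = engine.frame_averages(params)
    if noise_sigma0 == 0.0:
        return [TimeActivityCurve(schedule, clean.copy()) for _ in range(n_rep)]
    rng = np.random.default_rng(seed)
    sd = _noise_sd(clean, schedule.durations, noise_sigma0)
    out = []
    for _ in range(n_rep):
        noisy = clean + rng.normal(0.0, 1.0, clean.shape) * sd
        out.append(TimeActivityCurve(schedule, noisy, allow_negative=True))
    return out


def tissue_concentration_tac(params: KineticParams, cp: InputFunction,
                             schedule: FrameSchedule) -> TimeActivityCurve:
    """Frame-averaged total tissue concentration C_d + C_a (no weighting).

    This is the blood-free curve classical Patlak analysis assumes; its
    late-time Patlak slope equals the macro influx rate K1*k3/(k2+k3).  The
    weighted ROI signal, by contrast, has asymptotic slope w_a * Ki because
    only the trapped pool contributes slope.
    """
    engine = FrameAveragedModel(cp, schedule)
    _, avg_cd, avg_ca = engine.frame_average_components(params)
    return TimeActivityCurve(schedule, avg_cd + avg_ca)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, kinetics and noise of the digital mouse-like phantom.

    A muscle "body" ellipsoid fills most of the grid; a blood-pool sphere
    (pure plasma signal, the left-ventricle stand-in) and a tumor sphere sit
    inside it.  The hypoxic core is the ``hypoxic_fraction`` of tumor voxels
    nearest the tumor center (rounded; exact by construction), the remainder
    is the normoxic rim.
    """

    shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: tuple[float, float, float] = (0.8, 0.8, 0.8)
    tumor_center: tuple[float, float, float] = (21.0, 21.0, 16.0)
    tumor_radius: float = 6.0
    hypoxic_fraction: float = 0.30
    blood_center: tuple[float, float, float] = (9.0, 9.0, 16.0)
    blood_radius: float = 3.0
    core_params: KineticParams = PRESETS["MDA-1h"]
    rim_params: KineticParams = KineticParams(K1=0.0255, k2=0.00286, k3=0.002,
                                              **_PRESET_WEIGHTS)
    muscle_params: KineticParams = KineticParams(K1=0.03, k2=0.03, k3=0.0005,
                                                 **_PRESET_WEIGHTS)
    noise_sigma0: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.hypoxic_fraction <= 1.0:
            raise InvalidSpecError("hypoxic fraction must lie in [0, 1]")
        if any(n < 8 for n in self.shape):
            raise InvalidSpecError("phantom grid too small")
        d = np.linalg.norm(np.subtract(self.tumor_center, self.blood_center))
        if d <= self.tumor_radius + self.blood_radius:
            raise InvalidSpecError("tumor and blood-pool spheres overlap")


@dataclass(frozen=True)
class PhantomResult:
    """Simulated 4D image with ground truth for oracle comparisons."""

    image4d: np.ndarray
    schedule: FrameSchedule
    masks: dict[str, RegionMask]
    true_ki: np.ndarray          # macro Ki, mL/g/min, NaN outside the body
    true_ki_apparent: np.ndarray  # w_a * Ki: what voxel Patlak on the weighted signal measures
    true_k3: np.ndarray          # 1/min, NaN outside the body
    region_tacs: dict[str, TimeActivityCurve]   # noiseless model TACs
    region_params: dict[str, KineticParams]
    spec: PhantomSpec


def _sphere(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def simulate_dynamic_pet(spec: PhantomSpec, cp: InputFunction,
                         schedule: FrameSchedule) -> PhantomResult:
    """Render the phantom's 4D dynamic image plus ground-truth masks and maps."""
    shape = spec.shape
    body = _sphere(shape, tuple((n - 1) / 2.0 for n in shape),
                   min(shape) / 2.0 - 1.0)
    tumor = _sphere(shape, spec.tumor_center, spec.tumor_radius) & body
    blood = _sphere(shape, spec.blood_center, spec.blood_radius) & body
    if not tumor.any() or not blood.any():
        raise InvalidSpecError("tumor or blood sphere lies outside the body")
    if (tumor & blood).any():
        raise InvalidSpecError("tumor and blood regions overlap")
    # hypoxic core: exactly round(fraction * n_tumor) voxels nearest the center
    tidx = np.argwhere(tumor)
    d2 = ((tidx - np.asarray(spec.tumor_center)) ** 2).sum(axis=1)
    order = np.lexsort((tidx[:, 2], tidx[:, 1], tidx[:, 0], d2))
    n_core = int(round(spec.hypoxic_fraction * tidx.shape[0]))
    core = np.zeros(shape, dtype=bool)
    for i, j, k in tidx[order[:n_core]]:
        core[i, j, k] = True
    rim = tumor & ~core
    muscle = body & ~tumor & ~blood
    blood_params = KineticParams(K1=0.0, k2=0.0, k3=0.0, w_p=1.0, w_d=0.0, w_a=0.0)
    regions = {
        "core": (core, spec.core_params),
        "rim": (rim, spec.rim_params),
        "muscle": (muscle, spec.muscle_params),
        "blood": (blood, blood_params),
    }
    engine = FrameAveragedModel(cp, schedule)
    image = np.zeros(shape + (schedule.n_frames,), dtype=float)
    true_ki = np.full(shape, np.nan)
    true_ki_apparent = np.full(shape, np.nan)
    true_k3 = np.full(shape, np.nan)
    region_tacs: dict[str, TimeActivityCurve] = {}
    region_params: dict[str, KineticParams] = {}
    for name, (mask, params) in regions.items():
        clean = engine.frame_averages(params)
        region_tacs[name] = TimeActivityCurve(schedule, clean)
        region_params[name] = params
        image[mask] = clean
        if mask.any():
            true_k3[mask] = params.k3
            try:
                ki = macro_influx_rate(params)
            except Exception:
                ki = 0.0
            true_ki[mask] = ki
            true_ki_apparent[mask] = params.w_a * ki
    if spec.noise_sigma0 > 0:
        rng = np.random.default_rng(spec.seed)
        sd = _noise_sd(image, schedule.durations, spec.noise_sigma0)
        image = image + rng.normal(0.0, 1.0, image.shape) * sd
    vox = spec.voxel_size_mm
    masks = {name: RegionMask(mask, vox, label=name)
             for name, (mask, _) in regions.items()}
    masks["tumor"] = RegionMask(tumor, vox, label="tumor")
    masks["body"] = RegionMask(body, vox, label="body")
    return PhantomResult(image4d=image, schedule=schedule, masks=masks,
                         true_ki=true_ki, true_ki_apparent=true_ki_apparent,
                         true_k3=true_k3,
                         region_tacs=region_tacs, region_params=region_params,
                         spec=spec)
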