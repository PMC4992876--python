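"""Time-frame bookkeeping and time-activity-curve containers.

A dynamic PET acquisition is reconstructed into contiguous time frames.
Frames are half-open intervals ``[start, end)`` in seconds from tracer
injection (injection coincides with acquisition start).  A time-activity
curve (TAC) holds one frame-averaged activity concentration per frame,
because PET frames integrate counts over their duration; model predictions
are therefore frame averages too, never midpoint samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidRecordError, InvalidSpecError

#: Physical half-life of fluorine-18, minutes.
F18_HALF_LIFE_MIN = 109.77


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping frame timeline in seconds post injection."""

    frame_start: np.ndarray
    frame_end: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.frame_start, dtype=float)
        end = np.asarray(self.frame_end, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_end", end)
        if start.ndim != 1 or start.shape != end.shape or start.size == 0:
            raise InvalidSpecError("frame_start/frame_end must be equal-length 1D arrays")
        if start[0] < 0:
            raise InvalidSpecError("schedule must not start before injection")
        if not np.all(end > start):
            raise InvalidSpecError("every frame must have positive duration")
        if not np.allclose(start[1:], end[:-1], rtol=0, atol=1e-9):
            raise InvalidSpecError("frames must be contiguous and non-overlapping")

    @property
    def n_frames(self) -> int:
        return self.frame_start.size

    @property
    def durations(self) -> np.ndarray:
        return self.frame_end - self.frame_start

    @property
    def total_duration(self) -> float:
        return float(self.frame_end[-1] - self.frame_start[0])

    def midpoints(self) -> np.ndarray:
        return frame_midpoints(self)


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-averaged activity concentration for one region or voxel.

    ``unit`` is a tag ("Bq/mL" or "%ID/g"); values are finite, and negative
    values are only admitted when ``allow_negative`` is set (frame noise in
    low-count reconstructions can undershoot zero).
    """

    schedule: FrameSchedule
    values: np.ndarray
    unit: str = "Bq/mL"
    allow_negative: bool = False

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (self.schedule.n_frames,):
            raise InvalidSpecError(
                f"expected {self.schedule.n_frames} frame values, got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise InvalidSpecError("TAC values must be finite")
        if not self.allow_negative and np.any(values < 0):
            raise InvalidSpecError(
                "negative TAC values require allow_negative=True (noise model)"
            )

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "TimeActivityCurve":
        return replace(self, values=np.asarray(values, dtype=float),
                       unit=self.unit if unit is None else unit)


@dataclass(frozen=True)
class InjectionRecord:
    """Injected dose and the tissue density used for %ID/g conversion."""

    injected_dose_bq: float
    injection_time_s: float = 0.0
    tissue_density_g_per_ml: float = 1.0

    def __post_init__(self):
        if not self.injected_dose_bq > 0:
            raise InvalidRecordError("injected dose must be positive")
        if not self.tissue_density_g_per_ml > 0:
            raise InvalidRecordError("tissue density must be positive")


def build_frame_schedule(spec: list[tuple[int, float]]) -> FrameSchedule:
    """Build a schedule from ``[(count, duration_s), ...]`` blocks.

    The conventional 2 h protocol ``[(10, 30), (10, 60), (10, 120),
    (10, 150), (12, 300)]`` yields 52 frames ending at 7200 s.
    """
    if not spec:
        raise InvalidSpecError("empty frame-schedule spec")
    durations = []
    for count, duration in spec:
        if int(count) != count or count < 1:
            raise InvalidSpecError(f"frame count must be a positive integer, got {count!r}")
        if not duration > 0:
            raise InvalidSpecError(f"frame duration must be positive, got {duration!r}")
        durations.extend([float(duration)] * int(count))
    end = np.cumsum(durations)
    start = np.concatenate([[0.0], end[:-1]])
    return FrameSchedule(start, end)


def frame_midpoints(schedule: FrameSchedule) -> np.ndarray:
    """Frame midpoints in seconds; strictly increasing by construction."""
    return 0.5 * (schedule.frame_start + schedule.frame_end)


def to_percent_id_per_gram(tac: TimeActivityCurve, inj: InjectionRecord) -> TimeActivityCurve:
    """Convert a Bq/mL TAC to percent injected dose per gram.

    ``%ID/g = 100 * (Bq/mL) / (injected dose in Bq * density in g/mL)``.
    Linear in activity, hence invertible by :func:`from_percent_id_per_gram`.
    """
    scale = 100.0 / (inj.injected_dose_bq * inj.tissue_density_g_per_ml)
    return tac.with_values(tac.values * scale, unit="%ID/g")


def from_percent_id_per_gram(tac: TimeActivityCurve, inj: InjectionRecord) -> TimeActivityCurve:
    """Inverse of :func:`to_percent_id_per_gram`."""
    scale = inj.injected_dose_bq * inj.tissue_density_g_per_ml / 100.0
    return tac.with_values(tac.values * scale, unit="Bq/mL")


def decay_correct(tac: TimeActivityCurve, half_life_min: float = F18_HALF_LIFE_MIN,
                  undo: bool = False) -> TimeActivityCurve:
    """Apply (or undo) radioactive-decay correction to injection time.

    Off by default in the pipeline: reconstructed PET images are normally
    already decay-corrected, and the kinetic model is radionuclide-agnostic.
    Correction uses the frame midpoint, adequate for frames short relative to
    the half-life.
    """
    if not half_life_min > 0:
        raise InvalidSpecError("half-life must be positive")
    lam = np.log(2.0) / (half_life_min * 60.0)  # 1/s
    factor = np.exp(lam * tac.schedule.midpoints())
    if undo:
        factor = 1.0 / factor
    return tac.with_values(tac.values * factor)
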