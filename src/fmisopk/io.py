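"""Readers/writers for the on-disk formats the pipeline touches.

Images travel as NIfTI (via nibabel), TACs and Patlak points as CSV (via
pandas), schedules/parameters/results as JSON.  These are deliberately plain
formats so runs diff cleanly and round-trip losslessly at float32 precision
for images and full precision for tabular data.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError
from .fitting import FitConfig, FitResult
from .kinetics import InputFunction, KineticParams
from .patlak import PatlakPoints
from .roi import RegionMask
from .tac import FrameSchedule, TimeActivityCurve, build_frame_schedule

__all__ = [
    "read_image4d", "read_image3d", "write_image",
    "read_tac_csv", "write_tac_csv",
    "read_input_function_csv", "write_input_function_csv",
    "read_schedule_json", "write_schedule_json",
    "read_params_json", "write_params_json",
    "write_fit_result_json", "write_patlak_csv",
    "read_mask", "write_mask",
]


# ---------------------------------------------------------------------------
# images

def _load_nifti(path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float32)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms


def read_image4d(path, schedule: FrameSchedule | None = None
                 ) -> tuple[np.ndarray, tuple[float, ...]]:
    """Load a 4D dynamic image -> (data (x,y,z,t) float32, voxel spacing mm).

    If a schedule is given, the frame count is checked against it.
    """
    data, zooms = _load_nifti(path)
    if data.ndim != 4:
        raise FormatError(f"{path}: expected a 4D image, got {data.ndim}D")
    if schedule is not None and data.shape[3] != schedule.n_frames:
        raise ConsistencyError(
            f"{path}: {data.shape[3]} frames but schedule has {schedule.n_frames}"
        )
    return data, zooms


def read_image3d(path) -> tuple[np.ndarray, tuple[float, ...]]:
    """Load a 3D volume (e.g. a parametric map or a single frame)."""
    data, zooms = _load_nifti(path)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D image, got {data.ndim}D")
    return data, zooms


def write_image(volume: np.ndarray, path, voxel_size_mm=(1.0, 1.0, 1.0),
                description: str = "") -> None:
    """Write a 3D/4D volume as float32 NIfTI with diagonal affine."""
    volume = np.asarray(volume, dtype=np.float32)
    if volume.ndim not in (3, 4):
        raise FormatError("only 3D/4D volumes are supported")
    affine = np.diag(list(voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(volume, affine)
    img.header.set_zooms(tuple(voxel_size_mm) + ((1.0,) if volume.ndim == 4 else ()))
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))


def read_mask(path, label: str = "") -> RegionMask:
    data, zooms = read_image3d(path)
    return RegionMask(data > 0.5, zooms, label=label)


def write_mask(mask: RegionMask, path) -> None:
    write_image(mask.mask.astype(np.float32), path, mask.voxel_size_mm,
                description=mask.label)


# ---------------------------------------------------------------------------
# TACs and input functions

def write_tac_csv(tac: TimeActivityCurve, path) -> None:
    """Columns: frame_start_s, frame_end_s, value, unit (header required)."""
    pd.DataFrame({
        "frame_start_s": tac.schedule.frame_start,
        "frame_end_s": tac.schedule.frame_end,
        "value": tac.values,
        "unit": tac.unit,
    }).to_csv(path, index=False)


def read_tac_csv(path) -> TimeActivityCurve:
    df = pd.read_csv(path)
    required = {"frame_start_s", "frame_end_s", "value", "unit"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: TAC CSV needs columns {sorted(required)}")
    schedule = FrameSchedule(df["frame_start_s"].to_numpy(float),
                             df["frame_end_s"].to_numpy(float))
    values = df["value"].to_numpy(float)
    return TimeActivityCurve(schedule, values, unit=str(df["unit"].iloc[0]),
                             allow_negative=bool(np.any(values < 0)))


def write_input_function_csv(cp: InputFunction, path) -> None:
    """Columns: time_s, value."""
    pd.DataFrame({"time_s": cp.sample_times,
                  "value": cp.plasma_concentration}).to_csv(path, index=False)


def read_input_function_csv(path) -> InputFunction:
    df = pd.read_csv(path)
    if not {"time_s", "value"}.issubset(df.columns):
        raise FormatError(f"{path}: input-function CSV needs columns time_s, value")
    return InputFunction(df["time_s"].to_numpy(float), df["value"].to_numpy(float))


def write_patlak_csv(points: PatlakPoints, path) -> None:
    pd.DataFrame({"frame_index": points.frame_index, "t_min": points.t_min,
                  "x": points.x, "y": points.y,
                  "valid": points.valid}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# JSON configs/results

def write_schedule_json(blocks: list[tuple[int, float]], path) -> None:
    """Schedule as a list of {count, duration_s} blocks."""
    Path(path).write_text(json.dumps(
        [{"count": int(c), "duration_s": float(d)} for c, d in blocks], indent=2))


def read_schedule_json(path) -> FrameSchedule:
    blocks = json.loads(Path(path).read_text())
    try:
        spec = [(b["count"], b["duration_s"]) for b in blocks]
    except (TypeError, KeyError) as exc:
        raise FormatError(f"{path}: schedule JSON must be a list of "
                          "{count, duration_s} objects") from exc
    return build_frame_schedule(spec)


def write_params_json(params: KineticParams, path) -> None:
    Path(path).write_text(json.dumps({
        "K1": params.K1, "k2": params.k2, "k3": params.k3, "k4": params.k4,
        "wp": params.w_p, "wd": params.w_d, "wa": params.w_a}, indent=2))


def read_params_json(path) -> KineticParams:
    d = json.loads(Path(path).read_text())
    try:
        return KineticParams(K1=d["K1"], k2=d["k2"], k3=d["k3"],
                             k4=d.get("k4", 0.0), w_p=d["wp"], w_d=d["wd"],
                             w_a=d["wa"])
    except KeyError as exc:
        raise FormatError(f"{path}: missing kinetic-parameter key {exc}") from exc


def fit_result_to_dict(result: FitResult) -> dict:
    p = result.params
    return {
        "params": {"K1": p.K1, "k2": p.k2, "k3": p.k3, "k4": p.k4,
                   "wp": p.w_p, "wd": p.w_d, "wa": p.w_a},
        "Ki_macro": p.K1 * p.k3 / (p.k2 + p.k3) if (p.k2 + p.k3) > 0 else None,
        "epsilon_percent": result.epsilon,
        "converged": result.converged,
        "n_iter": result.n_iter,
        "n_starts_used": result.n_starts_used,
        "sse": result.sse,
        "residuals": result.residuals.tolist(),
    }


def write_fit_result_json(result: FitResult, path) -> None:
    Path(path).write_text(json.dumps(fit_result_to_dict(result), indent=2))


def fit_config_from_dict(d: dict) -> FitConfig:
    known = {f.name for f in dataclasses.fields(FitConfig)}
    unknown = set(d) - known
    if unknown:
        raise FormatError(f"unknown fit-config keys {sorted(unknown)}")
    return FitConfig(**d)
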