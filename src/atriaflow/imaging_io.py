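"""Reading and writing dynamic series, label maps, parametric maps and reports.

All volumes travel as NIfTI-1 (via nibabel); frame timing, label legends and
reports are JSON (NIfTI has no standard place for a 4D frame schedule, so it
rides in a sidecar with fixed field names ``frame_start_s`` /
``frame_duration_s`` for bit-exact interchange).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, GeometryError, ScheduleError

#: Fixed integer codes of the output label map.
LABEL_CODES: dict[str, int] = {
    "lv_myocardium": 1,
    "rv_myocardium": 2,
    "lv_cavity": 3,
    "rv_cavity": 4,
    "left_atrium": 5,
    "right_atrium": 6,
    "aorta": 7,
    "svc": 8,
}


def default_frame_schedule() -> tuple[np.ndarray, np.ndarray]:
    """The 22-frame, 6-minute dynamic protocol (starts and durations, s).

    1x10 s, 8x5 s, 4x10 s, 2x15 s, 3x20 s, 2x30 s, 2x60 s.
    """
    durations = np.array(
        [10.0] + [5.0] * 8 + [10.0] * 4 + [15.0] * 2 + [20.0] * 3 + [30.0] * 2 + [60.0] * 2
    )
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return starts, durations


def validate_schedule(frame_start: np.ndarray, frame_duration: np.ndarray) -> None:
    frame_start = np.asarray(frame_start, float)
    frame_duration = np.asarray(frame_duration, float)
    if frame_start.ndim != 1 or frame_start.shape != frame_duration.shape:
        raise ScheduleError("frame_start and frame_duration must be 1-D and equal length")
    if frame_start.size == 0:
        raise ScheduleError("empty frame schedule")
    if np.any(frame_duration <= 0):
        raise ScheduleError("frame durations must be positive")
    if abs(frame_start[0]) > 1e-6:
        raise ScheduleError("schedule must start at t = 0")
    gaps = frame_start[1:] - (frame_start[:-1] + frame_duration[:-1])
    if np.any(np.abs(gaps) > 1e-6):
        raise ScheduleError("schedule must be contiguous and non-overlapping")


@dataclass
class DynamicSeries:
    """A 4D dynamic PET series: activity (kBq/mL) per voxel per frame.

    ``data`` is indexed (x, y, z, frame); world coordinates are
    ``voxel index * voxel_size`` (mm), matching the stored affine.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    frame_start: np.ndarray
    frame_duration: np.ndarray
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.frame_start = np.asarray(self.frame_start, float)
        self.frame_duration = np.asarray(self.frame_duration, float)
        if self.data.ndim != 4:
            raise FormatError("dynamic series must be 4-D (x, y, z, frame)")
        validate_schedule(self.frame_start, self.frame_duration)
        if self.data.shape[3] != self.frame_start.size:
            raise FormatError(
                f"frame count mismatch: data has {self.data.shape[3]} frames, "
                f"schedule has {self.frame_start.size}"
            )
        if any(v <= 0 for v in self.voxel_size):
            raise GeometryError("voxel sizes must be positive")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])

    @property
    def n_frames(self) -> int:
        return int(self.frame_start.size)

    @property
    def frame_mid(self) -> np.ndarray:
        return self.frame_start + 0.5 * self.frame_duration

    @property
    def total_duration_s(self) -> float:
        return float(self.frame_start[-1] + self.frame_duration[-1])

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


def save_dynamic_series(series: DynamicSeries, image_path: str | Path, timing_path: str | Path) -> None:
    img = nib.Nifti1Image(series.data.astype(np.float32), series.affine)
    img.header.set_zooms(tuple(series.voxel_size) + (1.0,))
    nib.save(img, str(image_path))
    timing = {
        "frame_start_s": [float(x) for x in series.frame_start],
        "frame_duration_s": [float(x) for x in series.frame_duration],
    }
    Path(timing_path).write_text(json.dumps(timing, indent=2) + "\n")


def load_dynamic_series(image_path: str | Path, timing_path: str | Path) -> DynamicSeries:
    """Load a 4D NIfTI plus its JSON frame-timing sidecar."""
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 4:
        raise FormatError(f"{image_path}: expected a 4-D image, got {data.ndim}-D")
    try:
        timing = json.loads(Path(timing_path).read_text())
        starts = np.asarray(timing["frame_start_s"], float)
        durs = np.asarray(timing["frame_duration_s"], float)
    except (KeyError, json.JSONDecodeError) as exc:
        raise FormatError(f"{timing_path}: invalid frame-timing sidecar") from exc
    if data.shape[3] != starts.size:
        raise FormatError(
            f"frame count mismatch: image has {data.shape[3]} frames, sidecar {starts.size}"
        )
    zooms = img.header.get_zooms()[:3]
    return DynamicSeries(
        data=data,
        voxel_size=tuple(float(z) for z in zooms),
        frame_start=starts,
        frame_duration=durs,
        affine=np.asarray(img.affine),
    )


def _volume_image(vol: np.ndarray, voxel_size, dtype) -> nib.Nifti1Image:
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol).astype(dtype), affine)
    img.header.set_zooms(tuple(voxel_size))
    return img


def save_volume(vol: np.ndarray, voxel_size, path: str | Path, *, integer: bool = False) -> None:
    dtype = np.int16 if integer else np.float32
    nib.save(_volume_image(vol, voxel_size, dtype), str(path))


def load_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def save_label_map(labels: np.ndarray, voxel_size, path: str | Path, legend_path: str | Path) -> None:
    """Write the integer chamber label map with its JSON legend.

    The legend maps every structure name to its fixed code; codes absent
    from the volume are still listed so downstream tools can rely on them.
    """
    save_volume(labels, voxel_size, path, integer=True)
    Path(legend_path).write_text(json.dumps(LABEL_CODES, indent=2) + "\n")


def save_outputs(
    labels: np.ndarray,
    maps: dict[str, np.ndarray],
    report,
    voxel_size,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Persist the pipeline products: label map, parametric maps, report.

    ``maps`` is a name -> 3D-array dict (e.g. tmid_s, auc_norm, mbf, ptf,
    v_a, v_rv); every map must share the label grid. ``report`` is any
    object exposing ``to_dict()`` (a :class:`~atriaflow.atria.VolumeReport`).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, vol in maps.items():
        if vol.shape != labels.shape:
            raise GeometryError(f"map '{name}' shape {vol.shape} != labels {labels.shape}")
        p = out / f"{name}.nii.gz"
        save_volume(vol, voxel_size, p)
        written[name] = p
    save_label_map(labels, voxel_size, out / "labels.nii.gz", out / "labels_legend.json")
    written["labels"] = out / "labels.nii.gz"
    written["legend"] = out / "labels_legend.json"
    rep = report.to_dict()
    (out / "report.json").write_text(json.dumps(rep, indent=2) + "\n")
    pd.DataFrame([rep]).to_csv(out / "report.csv", index=False)
    written["report_json"] = out / "report.json"
    written["report_csv"] = out / "report.csv"
    return written
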