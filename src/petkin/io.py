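"""File formats: TAC CSV, NIfTI images with schedule sidecars, manifests.

TAC files are plain CSV with the header
``frame_start_min,frame_duration_min,activity_kBq_ml`` and round-trip
bit-exact on text.  Dynamic images and label maps travel as NIfTI
(.nii/.nii.gz) with the frame schedule in a JSON sidecar, since NIfTI
carries no per-frame timing.  Every CLI run writes a JSON manifest
(config, seed, package version) next to its outputs so results are
reproducible from the manifest alone.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from .aif import TimeActivityCurve
from .imaging import DynamicImage, LabelMap
from .protocol import FrameSchedule

__all__ = [
    "read_tac",
    "write_tac",
    "save_dynamic_image",
    "load_dynamic_image",
    "save_label_map",
    "load_label_map",
    "save_parameter_map",
    "write_manifest",
]

TAC_COLUMNS = ("frame_start_min", "frame_duration_min", "activity_kBq_ml")


def write_tac(curve: TimeActivityCurve, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            TAC_COLUMNS[0]: curve.schedule.start,
            TAC_COLUMNS[1]: curve.schedule.duration,
            TAC_COLUMNS[2]: curve.activity,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_tac(path: str | Path) -> TimeActivityCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TAC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"TAC file missing columns: {sorted(missing)}")
    schedule = FrameSchedule(
        df[TAC_COLUMNS[0]].to_numpy(), df[TAC_COLUMNS[1]].to_numpy()
    )
    return TimeActivityCurve(schedule, df[TAC_COLUMNS[2]].to_numpy())


def _affine(voxel_size) -> np.ndarray:
    return np.diag([*voxel_size, 1.0])


def save_dynamic_image(image: DynamicImage, path: str | Path) -> None:
    """Write a 4D NIfTI plus a ``<stem>.json`` frame-schedule sidecar."""
    path = Path(path)
    nib.save(
        nib.Nifti1Image(image.data.astype(np.float32), _affine(image.voxel_size)),
        path,
    )
    sidecar = {
        "frame_start_min": image.schedule.start.tolist(),
        "frame_duration_min": image.schedule.duration.tolist(),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def load_dynamic_image(path: str | Path) -> DynamicImage:
    path = Path(path)
    img = nib.load(path)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    meta = json.loads(_sidecar_path(path).read_text())
    schedule = FrameSchedule(
        np.asarray(meta["frame_start_min"]), np.asarray(meta["frame_duration_min"])
    )
    return DynamicImage(np.asarray(img.dataobj, dtype=float), voxel_size, schedule)


def save_label_map(labels: LabelMap, path: str | Path) -> None:
    path = Path(path)
    nib.save(
        nib.Nifti1Image(labels.labels.astype(np.int16), _affine(labels.voxel_size)),
        path,
    )
    _sidecar_path(path).write_text(
        json.dumps({str(k): v for k, v in labels.regions.items()}, indent=1)
    )


def load_label_map(path: str | Path) -> LabelMap:
    path = Path(path)
    img = nib.load(path)
    regions = {
        int(k): v for k, v in json.loads(_sidecar_path(path).read_text()).items()
    }
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelMap(np.asarray(img.dataobj, dtype=np.int16), regions, voxel_size)


def save_parameter_map(
    values: np.ndarray, voxel_size, path: str | Path
) -> None:
    nib.save(
        nib.Nifti1Image(np.asarray(values, dtype=np.float32), _affine(voxel_size)),
        Path(path),
    )


def write_manifest(path: str | Path, config: Mapping[str, Any]) -> None:
    """Record the exact run configuration (plus package version)."""
    from . import __version__

    payload = dict(config)
    payload["petkin_version"] = __version__
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
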