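"""NIfTI-1 and sidecar I/O for phantom datasets and quantification maps."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import PhantomData, label_table
from .schedule import OffsetSchedule

__all__ = [
    "save_nifti",
    "load_nifti",
    "write_phantom",
    "read_cest_dataset",
    "write_dwi",
    "read_dwi",
    "write_schedule_json",
    "read_schedule_json",
]

_IDENTITY = np.eye(4)


def save_nifti(data: np.ndarray, path: Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), _IDENTITY), str(path))


def load_nifti(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def write_schedule_json(schedule: OffsetSchedule, path: Path) -> None:
    payload = {
        "entries": [[float(o), int(n)] for o, n in schedule.entries],
        "includes_unsaturated": schedule.includes_unsaturated,
        "acquisition_offsets": [float(o) for o in schedule.acquisition_offsets()],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_schedule_json(path: Path) -> OffsetSchedule:
    payload = json.loads(Path(path).read_text())
    return OffsetSchedule(
        tuple((float(o), int(n)) for o, n in payload["entries"]),
        payload.get("includes_unsaturated", True),
    )


def write_phantom(data: PhantomData, out_dir: Path) -> dict[str, Path]:
    """Write one subject's CEST dataset: 4-D saturation stack (one volume
    per acquisition, order in the JSON sidecar), unsaturated volume, label
    mask with its code table, and the true B0 map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "stack": out / "cest_stack.nii.gz",
        "s0": out / "cest_s0.nii.gz",
        "labels": out / "labels.nii.gz",
        "b0": out / "b0_true.nii.gz",
        "schedule": out / "schedule.json",
        "label_table": out / "labels.json",
    }
    save_nifti(data.stack, paths["stack"])
    save_nifti(data.unsaturated, paths["s0"])
    nib.save(nib.Nifti1Image(data.labels.astype(np.int16), _IDENTITY), str(paths["labels"]))
    save_nifti(data.b0_map, paths["b0"])
    write_schedule_json(data.schedule, paths["schedule"])
    paths["label_table"].write_text(
        json.dumps({str(k): list(v) for k, v in label_table().items()}, indent=1)
    )
    return paths


def read_cest_dataset(subject_dir: Path) -> PhantomData:
    d = Path(subject_dir)
    return PhantomData(
        stack=load_nifti(d / "cest_stack.nii.gz"),
        unsaturated=load_nifti(d / "cest_s0.nii.gz"),
        labels=load_nifti(d / "labels.nii.gz").astype(np.int16),
        b0_map=load_nifti(d / "b0_true.nii.gz"),
        schedule=read_schedule_json(d / "schedule.json"),
    )


def write_dwi(dwi: np.ndarray, bvals: np.ndarray, bvecs: np.ndarray, out_dir: Path) -> dict[str, Path]:
    """4-D DWI volume with FSL-style plain-text bval/bvec files
    (bvecs written as 3 rows of n columns)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "dwi": out / "dwi.nii.gz",
        "bval": out / "dwi.bval",
        "bvec": out / "dwi.bvec",
    }
    save_nifti(dwi, paths["dwi"])
    paths["bval"].write_text(" ".join(f"{b:g}" for b in bvals) + "\n")
    lines = [" ".join(f"{v:.6f}" for v in np.asarray(bvecs)[:, i]) for i in range(3)]
    paths["bvec"].write_text("\n".join(lines) + "\n")
    return paths


def read_dwi(out_dir: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = Path(out_dir)
    dwi = load_nifti(d / "dwi.nii.gz")
    bvals = np.loadtxt(d / "dwi.bval")
    bvecs = np.loadtxt(d / "dwi.bvec").T
    return dwi, bvals, bvecs


def write_roi_csv(table: pd.DataFrame, path: Path) -> None:
    table.to_csv(path, index=False, float_format="%.10g")


def read_roi_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path)
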