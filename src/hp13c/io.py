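"""NIfTI and tabular plumbing for synthetic studies and derived maps."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .acquisition import METABOLITES, AcquisitionParams, DynamicMetaboliteImage
from .rois import MaskSet

__all__ = [
    "save_nifti",
    "load_nifti",
    "array_sha256",
    "write_study",
    "load_study_dynamics",
    "load_study_masks",
    "write_json",
]


def _affine(voxel_mm) -> np.ndarray:
    if np.isscalar(voxel_mm):
        voxel_mm = (voxel_mm, voxel_mm, voxel_mm)
    return np.diag([voxel_mm[0], voxel_mm[1], voxel_mm[2], 1.0])


def save_nifti(arr: np.ndarray, path, voxel_mm) -> Path:
    """Write an array as NIfTI with a diagonal voxel-size affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(arr)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32), _affine(voxel_mm))
    nib.save(img, str(path))
    return path


def load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Load a NIfTI volume; returns (array, voxel dimensions in mm)."""
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata()), zooms


def array_sha256(arr: np.ndarray) -> str:
    """Content hash of an array (shape, dtype and raw bytes)."""
    arr = np.ascontiguousarray(arr)
    h = hashlib.sha256()
    h.update(str(arr.shape).encode())
    h.update(str(arr.dtype).encode())
    h.update(arr.tobytes())
    return h.hexdigest()


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
    return path


# ---------------------------------------------------------------------------
# study layout on disk
# ---------------------------------------------------------------------------

_MASK_NAMES = ("brain", "t2l", "cel", "wm")


def write_study(study, outdir) -> dict[str, str]:
    """Write a synthetic study: 4D dynamics, 1H masks, truth maps, clinical CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for m in METABOLITES:
        p = save_nifti(study.dynamics[m].data, outdir / f"dynamic_{m}.nii.gz", study.config.voxel_13c)
        paths[f"dynamic_{m}"] = str(p)
    for name in _MASK_NAMES:
        p = save_nifti(getattr(study.masks, name), outdir / f"mask_{name}.nii.gz", study.masks.voxel_mm)
        paths[f"mask_{name}"] = str(p)
    for name, arr in (("truth_kpl", study.truth_kpl), ("truth_kpb", study.truth_kpb)):
        p = save_nifti(arr, outdir / f"{name}.nii.gz", study.config.voxel_13c)
        paths[name] = str(p)
    clinical = outdir / "clinical.csv"
    pd.DataFrame([study.clinical_row]).to_csv(clinical, index=False)
    paths["clinical"] = str(clinical)
    return paths


def load_study_dynamics(study_dir, params: AcquisitionParams) -> dict[str, DynamicMetaboliteImage]:
    """Load per-metabolite 4D dynamics written by :func:`write_study`."""
    study_dir = Path(study_dir)
    dynamics = {}
    for m in METABOLITES:
        arr, zooms = load_nifti(study_dir / f"dynamic_{m}.nii.gz")
        dynamics[m] = DynamicMetaboliteImage(data=arr, metabolite=m, voxel_mm=zooms[0], params=params)
    return dynamics


def load_study_masks(study_dir) -> MaskSet:
    """Load the 1H-resolution anatomical masks written by :func:`write_study`."""
    study_dir = Path(study_dir)
    arrays = {}
    zooms = (1.0, 1.0, 1.0)
    for name in _MASK_NAMES:
        arr, zooms = load_nifti(study_dir / f"mask_{name}.nii.gz")
        arrays[name] = arr > 0.5
    return MaskSet(voxel_mm=zooms, **arrays)
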