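"""NIfTI / FSL-sidecar I/O helpers (identity affine, RAS, mm units)."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_bvals_bvecs",
    "load_bvals_bvecs",
    "save_echo_times",
    "load_echo_times",
]


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] *= voxel_size_mm
    return aff


def save_nifti(path, data: np.ndarray, voxel_size_mm: float = 1.0) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, np.float32), _affine(voxel_size_mm))
    nib.save(img, str(path))
    return path


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_bvals_bvecs(prefix, bvals, bvecs) -> tuple[Path, Path]:
    """FSL convention: bvals one row; bvecs three rows (x, y, z)."""
    prefix = Path(prefix)
    bval_path = prefix.with_suffix(".bval")
    bvec_path = prefix.with_suffix(".bvec")
    np.savetxt(bval_path, np.asarray(bvals, float)[None, :], fmt="%.1f")
    np.savetxt(bvec_path, np.asarray(bvecs, float).reshape(-1, 3).T, fmt="%.6f")
    return bval_path, bvec_path


def load_bvals_bvecs(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return bvals, bvecs


def save_echo_times(path, times_ms) -> Path:
    path = Path(path)
    path.write_text(json.dumps({"t2prep_times_ms": list(map(float, times_ms))}, indent=2))
    return path


def load_echo_times(path) -> np.ndarray:
    return np.asarray(json.loads(Path(path).read_text())["t2prep_times_ms"], float)
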