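"""Perivascular-space (PVS) morphometry on the enhanced PVS contrast (EPC).

EPC is the T1w/T2w ratio image: PVS are CSF-filled, hence T2w-bright and
T1w-dark, so they appear as dark tubular structures on EPC.  Multi-scale
Frangi vesselness (Hessian eigenvalue analysis) highlights those tubes; the
vesselness map is thresholded, restricted to cerebral white matter with WMH
lesions excluded, small clusters are removed under 26-connectivity, and the
remaining PVS volume is normalized by the WM volume to give the burden
PVS/WMV (%).

The vesselness construction is the standard one

    V = (1 - e^{-R_A^2 / 2 alpha^2}) e^{-R_B^2 / 2 beta^2} (1 - e^{-S^2 / 2 c^2})

maximized over Gaussian scales, with V = 0 where the tube polarity is
violated; it is evaluated through scikit-image's Frangi filter (whose
``gamma=None`` default reproduces the "c = half the maximum Frobenius Hessian
norm per scale" rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import frangi as _skimage_frangi

__all__ = [
    "EpcVolume",
    "VesselnessParams",
    "PvsResult",
    "compute_epc",
    "frangi_vesselness",
    "segment_pvs",
    "pvs_burden",
    "pvs_analysis",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class EpcVolume:
    data: np.ndarray
    brain_mask: np.ndarray
    clipped: np.ndarray  # voxels where the T2w denominator was floored


@dataclass(frozen=True)
class VesselnessParams:
    """Frangi sensitivities: ``alpha`` (plate vs line), ``beta`` (blob),
    ``c`` (structureness; None = per-scale auto), scales in mm, and tube
    polarity ('dark' for PVS on EPC)."""

    scales_mm: tuple[float, ...] = (0.5, 1.0, 1.5)
    alpha: float = 0.5
    beta: float = 0.5
    c: float | None = None
    polarity: str = "dark"
    voxel_size_mm: float = 1.0

    def __post_init__(self):
        if len(self.scales_mm) == 0 or any(s <= 0 for s in self.scales_mm):
            raise ValueError("scales must be positive and nonempty")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.polarity not in ("dark", "bright"):
            raise ValueError("polarity must be 'dark' or 'bright'")


@dataclass
class PvsResult:
    pvs_mask: np.ndarray
    pvs_volume_mm3: float
    wm_volume_mm3: float
    burden_pct: float


def compute_epc(t1w: np.ndarray, t2w: np.ndarray, brain_mask: np.ndarray,
                eps: float = 1e-6) -> EpcVolume:
    """T1w/T2w ratio inside the mask, with the denominator floored at ``eps``
    (floored voxels are flagged)."""
    t1w = np.asarray(t1w, float)
    t2w = np.asarray(t2w, float)
    mask = np.asarray(brain_mask, bool)
    if t1w.shape != t2w.shape or t1w.shape != mask.shape:
        raise ValueError("t1w, t2w and mask must share one grid")
    if eps <= 0:
        raise ValueError("eps must be positive")
    clipped = (t2w < eps) & mask
    data = np.zeros_like(t1w)
    data[mask] = t1w[mask] / np.maximum(t2w[mask], eps)
    return EpcVolume(data=data, brain_mask=mask, clipped=clipped)


def frangi_vesselness(volume: np.ndarray, params: VesselnessParams | None = None) -> np.ndarray:
    """Multi-scale Frangi vesselness in [0, 1] (voxelwise maximum over
    scales).  Scales are interpreted in mm at ``params.voxel_size_mm``
    isotropic spacing; anisotropic grids should be resampled first."""
    params = params or VesselnessParams()
    vol = np.asarray(volume, float)
    if vol.ndim != 3:
        raise ValueError("expected a 3D volume")
    sigmas = [s / params.voxel_size_mm for s in params.scales_mm]
    if params.voxel_size_mm != 1.0:
        warnings.warn(
            "scales interpreted as sigma = scale_mm / voxel_size_mm on an "
            "isotropic grid", stacklevel=2,
        )
    v = _skimage_frangi(
        vol, sigmas=sigmas, alpha=params.alpha, beta=params.beta,
        gamma=params.c, black_ridges=(params.polarity == "dark"), mode="reflect",
    )
    return np.clip(v, 0.0, 1.0)


def segment_pvs(vesselness: np.ndarray, wm_mask: np.ndarray, wmh_mask: np.ndarray,
                threshold: float = 0.2, min_cluster_voxels: int = 2) -> np.ndarray:
    """(vesselness >= threshold) restricted to WM with WMH excluded; clusters
    smaller than ``min_cluster_voxels`` removed under 26-connectivity."""
    wm = np.asarray(wm_mask, bool)
    wmh = np.asarray(wmh_mask, bool)
    v = np.asarray(vesselness, float)
    if v.shape != wm.shape or v.shape != wmh.shape:
        raise ValueError("vesselness and masks must share one grid")
    if not wm.any():
        raise ValueError("WM mask is empty")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    mask = (v >= threshold) & wm & ~wmh
    if min_cluster_voxels > 1 and mask.any():
        lab, n = ndimage.label(mask, structure=_STRUCT_26)
        counts = np.bincount(lab.ravel())
        small = np.flatnonzero(counts < min_cluster_voxels)
        mask &= ~np.isin(lab, small[small > 0])
    return mask


def pvs_burden(pvs_mask: np.ndarray, wm_mask: np.ndarray,
               voxel_volume_mm3: float = 1.0) -> float:
    """PVS/WMV burden in percent: 100 * |PVS| / |WM| (voxel-volume exact)."""
    wm = np.asarray(wm_mask, bool)
    if not wm.any():
        raise ValueError("WM mask is empty")
    if voxel_volume_mm3 <= 0:
        raise ValueError("voxel volume must be positive")
    return 100.0 * float(np.count_nonzero(pvs_mask)) / float(np.count_nonzero(wm))


def pvs_analysis(epc: EpcVolume, wm_mask: np.ndarray, wmh_mask: np.ndarray,
                 params: VesselnessParams | None = None, threshold: float = 0.2,
                 min_cluster_voxels: int = 2, voxel_volume_mm3: float = 1.0) -> PvsResult:
    """EPC -> vesselness -> segmentation -> burden, in one call."""
    v = frangi_vesselness(epc.data, params)
    mask = segment_pvs(v, wm_mask, wmh_mask, threshold, min_cluster_voxels)
    nv = voxel_volume_mm3
    return PvsResult(
        pvs_mask=mask,
        pvs_volume_mm3=float(np.count_nonzero(mask)) * nv,
        wm_volume_mm3=float(np.count_nonzero(wm_mask)) * nv,
        burden_pct=pvs_burden(mask, wm_mask, nv),
    )
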