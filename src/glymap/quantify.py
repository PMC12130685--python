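"""Calibration of fraction maps to absolute glymphatic-fluid measures, ROI
extraction, and PET SUVR.

Fraction maps (pCSFF from relaxometry, DTI-FW from diffusion) measure a share
of voxel *water*; multiplying by the tissue total water content (TWC) converts
them to a share of voxel *volume*, the absolute measures pCSF and FW.  TWC is
taken constant at 83% in grey matter and 70% in white matter.  WM ROI means
exclude WMH lesions; amyloid burden is summarized as the mean PET uptake in a
cortical AD meta-ROI divided by the cerebellar-cortex reference (SUVR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TwcConstants",
    "calibrate_fraction_map",
    "roi_mean",
    "compute_suvr",
    "build_subject_table",
]

BIOMARKER_COLUMNS = ("wm_pcsf", "gm_pcsf", "admask_pcsf", "wm_fw", "pvs_wmv", "suvr")
COVARIATE_COLUMNS = ("age", "sex", "dx", "apoe4")


@dataclass(frozen=True)
class TwcConstants:
    """Tissue total water content (fraction of tissue volume)."""

    twc_gm: float = 0.83
    twc_wm: float = 0.70

    def __post_init__(self):
        for v in (self.twc_gm, self.twc_wm):
            if not 0.0 < v <= 1.0:
                raise ValueError("TWC values must lie in (0, 1]")


def calibrate_fraction_map(frac_map: np.ndarray, gm_mask: np.ndarray, wm_mask: np.ndarray,
                           twc: TwcConstants | None = None) -> np.ndarray:
    """Water-fraction map -> volume-fraction map: value * TWC_GM in GM,
    value * TWC_WM in WM, zero elsewhere.  Order-preserving within tissue."""
    twc = twc or TwcConstants()
    gm = np.asarray(gm_mask, bool)
    wm = np.asarray(wm_mask, bool)
    if (gm & wm).any():
        raise ValueError("GM and WM masks overlap")
    f = np.asarray(frac_map, float)
    out = np.zeros_like(f)
    out[gm] = f[gm] * twc.twc_gm
    out[wm] = f[wm] * twc.twc_wm
    return out


def roi_mean(volume: np.ndarray, roi_mask: np.ndarray,
             exclude_mask: np.ndarray | None = None, as_percent: bool = True) -> float:
    """Arithmetic mean over roi \\ exclude, reported in % of a [0, 1] map by
    default."""
    roi = np.asarray(roi_mask, bool)
    if exclude_mask is not None:
        roi = roi & ~np.asarray(exclude_mask, bool)
    if not roi.any():
        raise ValueError("effective ROI is empty")
    m = float(np.mean(np.asarray(volume, float)[roi]))
    return 100.0 * m if as_percent else m


def compute_suvr(pet: np.ndarray, target_mask: np.ndarray, ref_mask: np.ndarray) -> float:
    """mean(PET[target]) / mean(PET[reference])."""
    tgt = np.asarray(target_mask, bool)
    ref = np.asarray(ref_mask, bool)
    if not tgt.any() or not ref.any():
        raise ValueError("target and reference masks must be nonempty")
    ref_mean = float(np.mean(np.asarray(pet, float)[ref]))
    if ref_mean == 0.0:
        raise ValueError("reference-region mean uptake is zero")
    return float(np.mean(np.asarray(pet, float)[tgt])) / ref_mean


def build_subject_table(records, measurements) -> pd.DataFrame:
    """Assemble the per-subject analysis table (one row per subject, ordered
    by id; biomarkers in %, SUVR as a ratio).

    ``records`` are SubjectRecords; ``measurements`` maps subject id -> dict
    of measured biomarkers.  Subjects with missing stage outputs are dropped
    with a warning.
    """
    rows = []
    for rec in records:
        meas = measurements.get(rec.id)
        missing = [] if meas else list(BIOMARKER_COLUMNS)
        if meas:
            missing = [k for k in BIOMARKER_COLUMNS if k not in meas or meas[k] is None]
        if missing:
            warnings.warn(f"subject {rec.id}: missing {missing}; row dropped", stacklevel=2)
            continue
        rows.append({
            "id": rec.id, "age": rec.age, "sex": rec.sex, "dx": rec.dx, "apoe4": rec.apoe4,
            **{k: float(meas[k]) for k in BIOMARKER_COLUMNS},
        })
    cols = ["id", *COVARIATE_COLUMNS, *BIOMARKER_COLUMNS]
    table = pd.DataFrame(rows, columns=cols)
    return table.sort_values("id", kind="stable").reset_index(drop=True)
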