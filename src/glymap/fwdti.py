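"""Bi-tensor free-water-elimination diffusion modelling.

The voxel DWI signal is decomposed into an anisotropic tissue compartment and
an isotropic free-water compartment:

    S(b, g) = S0 [ (1 - f) e^{-b g'Dg} + f e^{-b d_iso} ]

where D is the symmetric tissue diffusion tensor, f the free-water fraction
(DTI-FW), and d_iso the diffusivity of free water at body temperature
(3.0e-3 mm^2/s).  Fitting requires at least two nonzero shells: from a single
shell, f and the mean tissue diffusivity trade off exactly and the model is
not identifiable, so single-shell input is refused.

The tensor is parameterized through its Cholesky factor, which keeps the
optimizer unconstrained in tensor space while guaranteeing a positive
semi-definite estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .phantom import IdentifiabilityError

__all__ = [
    "FwFit",
    "FwFitOptions",
    "bitensor_signal",
    "compute_fa",
    "single_tensor_loglinear",
    "fit_fw_voxel",
    "fit_fw_volume",
    "IdentifiabilityError",
]

D_ISO_DEFAULT = 3.0e-3  # mm^2/s, free water at 37 C

# optimizer works in um^2/ms (= 1e-3 mm^2/s) for conditioning
_SCALE = 1.0e-3


@dataclass(frozen=True)
class FwFitOptions:
    d_iso: float = D_ISO_DEFAULT
    f_init: float = 0.1
    fix_fw: float | None = None  # fit with f frozen (e.g. 0 for single-tensor nesting)
    max_nfev: int = 400


@dataclass
class FwFit:
    f_fw: float
    d_tissue: np.ndarray  # (3, 3) mm^2/s
    fa: float
    s0: float
    objective: float
    converged: bool


def _check_tensor(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, float)
    if d.shape[-2:] != (3, 3):
        raise ValueError("tensor must be 3x3")
    if not np.allclose(d, np.swapaxes(d, -1, -2), atol=1e-12):
        raise ValueError("tensor must be symmetric")
    return d


def bitensor_signal(d_tissue, f_fw: float, s0: float, bvals, bvecs,
                    d_iso: float = D_ISO_DEFAULT) -> np.ndarray:
    """Forward bi-tensor signal for one voxel; S = s0 at b = 0."""
    d = _check_tensor(d_tissue)
    if np.min(np.linalg.eigvalsh(d)) < -1e-9:
        raise ValueError("tissue tensor must be positive semi-definite")
    if d_iso <= 0:
        raise ValueError("d_iso must be positive")
    if not 0.0 <= f_fw <= 1.0:
        raise ValueError("f_fw must lie in [0, 1]")
    b = np.asarray(bvals, float)
    g = np.asarray(bvecs, float).reshape(-1, 3)
    q = np.einsum("vi,ij,vj->v", g, d, g)
    return s0 * ((1.0 - f_fw) * np.exp(-b * q) + f_fw * np.exp(-b * d_iso))


def compute_fa(d_tissue) -> float:
    """Fractional anisotropy from the tensor eigenvalues; 0 for the all-zero
    tensor by convention, rotation-invariant by construction."""
    d = _check_tensor(d_tissue)
    ev = np.linalg.eigvalsh(d)
    ss = float(np.sum(ev**2))
    if ss == 0.0:
        return 0.0
    md = ev.mean()
    fa = np.sqrt(1.5 * float(np.sum((ev - md) ** 2)) / ss)
    return float(min(max(fa, 0.0), 1.0))


def _validate_scheme(bvals: np.ndarray, bvecs: np.ndarray):
    nz = bvals > 0
    if not (~nz).any():
        raise ValueError("need at least one b=0 volume")
    shells = set(np.round(bvals[nz], 3))
    if len(shells) < 2:
        raise IdentifiabilityError(
            "bi-tensor fitting needs >= 2 nonzero shells; free water and mean "
            "diffusivity are not identifiable from a single shell"
        )
    dirs = {tuple(np.round(v, 6)) for v in bvecs[nz]}
    if len(dirs) < 6:
        raise IdentifiabilityError("need >= 6 unique nonzero gradient directions")


def single_tensor_loglinear(signal, bvals, bvecs) -> tuple[np.ndarray, float]:
    """Classic log-linear DTI fit (design matrix on log signal); returns
    (tensor mm^2/s, s0).  Used as the deterministic initialization."""
    b = np.asarray(bvals, float)
    g = np.asarray(bvecs, float).reshape(-1, 3)
    s = np.asarray(signal, float)
    s0 = float(np.mean(s[b == 0]))
    s0 = s0 if s0 > 0 else float(np.max(s)) or 1.0
    y = np.log(np.maximum(s, 1e-10) / s0)
    X = -b[:, None] * np.column_stack([
        g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
        2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
    ])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    dxx, dyy, dzz, dxy, dxz, dyz = coef
    d = np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])
    # clip to PSD for a valid Cholesky start
    w, v = np.linalg.eigh(d)
    w = np.clip(w, 1e-6, None)
    return v @ np.diag(w) @ v.T, s0


def _chol_to_tensor(c: np.ndarray) -> np.ndarray:
    L = np.array([[c[0], 0, 0], [c[1], c[2], 0], [c[3], c[4], c[5]]])
    return L @ L.T


def _tensor_to_chol(d: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(d + 1e-12 * np.eye(3))
    return np.array([L[0, 0], L[1, 0], L[1, 1], L[2, 0], L[2, 1], L[2, 2]])


def fit_fw_voxel(signal, bvals, bvecs, opts: FwFitOptions | None = None) -> FwFit:
    """Bounded nonlinear least squares over (f, Cholesky tensor, s0) for one
    voxel, initialized from the log-linear single-tensor fit with f = 0.1."""
    opts = opts or FwFitOptions()
    s = np.asarray(signal, float)
    b = np.asarray(bvals, float)
    g = np.asarray(bvecs, float).reshape(-1, 3)
    if s.size != b.size or b.size != g.shape[0]:
        raise ValueError("signal/bvals/bvecs lengths are inconsistent")
    if np.any(s < 0) or not np.all(np.isfinite(s)):
        raise ValueError("signals must be finite and nonnegative")
    _validate_scheme(b, g)

    d0, s0_init = single_tensor_loglinear(s, b, g)
    c0 = _tensor_to_chol(d0 / _SCALE)
    water = np.exp(-b * opts.d_iso)
    gouter = np.column_stack([
        g[:, 0] ** 2, 2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2],
        g[:, 1] ** 2, 2 * g[:, 1] * g[:, 2], g[:, 2] ** 2,
    ])  # row-major upper triangle weights for g'Dg

    fixed_f = opts.fix_fw

    def unpack(x):
        if fixed_f is None:
            f, s0 = x[6], x[7]
        else:
            f, s0 = fixed_f, x[6]
        return x[:6], f, s0

    def residuals(x):
        c, f, s0 = unpack(x)
        D = _chol_to_tensor(c) * _SCALE
        q = gouter @ np.array([D[0, 0], D[0, 1], D[0, 2], D[1, 1], D[1, 2], D[2, 2]])
        model = s0 * ((1.0 - f) * np.exp(-b * q) + f * water)
        return model - s

    chol_lo = [0.0, -10.0, 0.0, -10.0, -10.0, 0.0]
    if fixed_f is None:
        x0 = np.concatenate([c0, [min(max(opts.f_init, 1e-6), 1 - 1e-6), s0_init]])
        lo = np.array(chol_lo + [0.0, 0.0])
        hi = np.array([10.0] * 6 + [1.0, np.inf])
    else:
        x0 = np.concatenate([c0, [s0_init]])
        lo = np.array(chol_lo + [0.0])
        hi = np.array([10.0] * 6 + [np.inf])

    res = least_squares(residuals, np.clip(x0, lo, hi), bounds=(lo, hi), method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=opts.max_nfev)
    c, f, s0 = unpack(res.x)
    D = _chol_to_tensor(c) * _SCALE
    return FwFit(
        f_fw=float(f), d_tissue=D, fa=compute_fa(D), s0=float(s0),
        objective=float(np.sum(res.fun**2)), converged=bool(res.success),
    )


def fit_fw_volume(series, opts: FwFitOptions | None = None):
    """Voxelwise independent bi-tensor fits inside the brain mask; returns
    (fw_map, fa_map, failure_mask).  An empty mask yields empty (zero) maps."""
    opts = opts or FwFitOptions()
    data = np.asarray(series.data, float)
    mask = np.asarray(series.brain_mask, bool)
    if mask.shape != data.shape[:-1]:
        raise ValueError("mask grid does not match data grid")
    fw = np.zeros(mask.shape)
    fa = np.zeros(mask.shape)
    failure = np.zeros(mask.shape, dtype=bool)
    for idx in np.argwhere(mask):
        tix = tuple(idx)
        fit = fit_fw_voxel(data[tix], series.bvals, series.bvecs, opts)
        fw[tix] = fit.f_fw
        fa[tix] = fit.fa
        failure[tix] = not fit.converged
    return fw, fa, failure
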