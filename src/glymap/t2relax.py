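"""Three-water-compartment T2 relaxometry and parenchymal-CSF-fraction maps.

The voxel signal of a T2prep multi-echo series is modelled as a sum of three
exponentially decaying water pools -- myelin water (MW), intra/extra-cellular
water (IE), and parenchymal CSF -- each with its own T2 range:

    S(t) = M0 * [ f_mw e^{-t/T2_mw} + f_ie e^{-t/T2_ie} + f_csf e^{-t/T2_csf} ]

with f_mw + f_ie + f_csf = 1.  The CSF pool collects long-T2 water
(200--2000 ms); its fitted fraction is the parenchymal CSF fraction (pCSFF),
the quantity of interest for glymphatic-fluid mapping.  With only six echo
times the inversion is ill-posed, so the fit adds an L2 penalty pulling the
fraction vector toward a physiological prior:

    objective = ||S_model - S_data||^2 + lambda * ||f - f_prior||^2

The CSF T2 is fixed at 2000 ms by default: a 307.5 ms maximum T2prep time
cannot resolve T2 values far beyond the sampling window, and free CSF-like
water at 3 T relaxes with T2 ~ 2 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "T2PoolModel",
    "VoxelFit",
    "RelaxometryMaps",
    "predict_signal",
    "fit_voxel",
    "fit_volume",
    "grid_search_simplex",
]

_POOLS = ("mw", "ie", "csf")


@dataclass(frozen=True)
class T2PoolModel:
    """Pool bounds/initials and regularization for the three-compartment fit.

    ``lambda_reg=None`` selects the data-scaled default 0.01 * ||S_data||^2.
    ``t2_fixed=True`` freezes every T2 at its initial value (fractions-only
    fit); ``csf_t2_fixed`` freezes only the CSF pool (the default).
    """

    t2_bounds_ms: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"mw": (5.0, 40.0), "ie": (40.0, 200.0), "csf": (200.0, 2000.0)}
    )
    t2_init_ms: dict[str, float] = field(
        default_factory=lambda: {"mw": 20.0, "ie": 80.0, "csf": 2000.0}
    )
    csf_t2_fixed: bool = True
    t2_fixed: bool = False
    lambda_reg: float | None = None
    f_prior: tuple[float, float, float] = (0.10, 0.85, 0.05)

    def __post_init__(self):
        prev_hi = 0.0
        for pool in _POOLS:
            lo, hi = self.t2_bounds_ms[pool]
            if not (0 < lo < hi):
                raise ValueError(f"invalid T2 bounds for pool {pool!r}")
            if lo < prev_hi:
                raise ValueError("pool T2 bounds must be non-overlapping and ordered")
            prev_hi = hi
            if not lo <= self.t2_init_ms[pool] <= hi:
                raise ValueError(f"T2 init for pool {pool!r} outside its bounds")
        if abs(sum(self.f_prior) - 1.0) > 1e-9:
            raise ValueError("f_prior must sum to 1")
        if self.lambda_reg is not None and self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")

    def effective_lambda(self, signal: np.ndarray) -> float:
        if self.lambda_reg is not None:
            return float(self.lambda_reg)
        return 0.01 * float(np.sum(np.square(signal)))


@dataclass
class VoxelFit:
    f_mw: float
    f_ie: float
    f_csf: float
    t2_mw: float
    t2_ie: float
    t2_csf: float
    m0: float
    objective: float
    converged: bool

    @property
    def fractions(self) -> np.ndarray:
        return np.array([self.f_mw, self.f_ie, self.f_csf])

    @property
    def pcsff(self) -> float:
        return self.f_csf


@dataclass
class RelaxometryMaps:
    f_mw: np.ndarray
    f_ie: np.ndarray
    f_csf: np.ndarray
    t2_mw: np.ndarray
    t2_ie: np.ndarray
    t2_csf: np.ndarray
    m0: np.ndarray
    objective: np.ndarray
    failure_mask: np.ndarray
    brain_mask: np.ndarray

    @property
    def pcsff(self) -> np.ndarray:
        return self.f_csf


def predict_signal(fractions, t2_ms, m0: float, times_ms) -> np.ndarray:
    """Forward three-exponential signal; S(0) = M0 exactly."""
    f = np.asarray(fractions, float)
    t2 = np.asarray(t2_ms, float)
    t = np.asarray(times_ms, float)
    if np.any(t2 <= 0):
        raise ValueError("all T2 values must be positive")
    if np.any(f < -1e-12) or abs(f.sum() - 1.0) > 1e-6:
        raise ValueError("fractions must be nonnegative and sum to 1")
    if np.any(t < 0):
        raise ValueError("echo times must be nonnegative")
    return m0 * (np.exp(-t[:, None] / t2[None, :]) @ f)


def _free_t2_pools(model: T2PoolModel) -> list[str]:
    if model.t2_fixed:
        return []
    pools = ["mw", "ie"]
    if not model.csf_t2_fixed:
        pools.append("csf")
    return pools


def _residuals_and_jac(params, times, signal, t2_fixed_vals, free_pools, sqrt_lam, prior):
    """Residual vector [model - data, sqrt(lam)*(f - prior)] and its Jacobian.

    Parameters are the three pool amplitudes followed by the free T2s; the
    fractions are the normalized amplitudes, so M0 = sum(a) is implicit.
    """
    a = params[:3]
    t2 = t2_fixed_vals.copy()
    for k, pool in enumerate(free_pools):
        t2[_POOLS.index(pool)] = params[3 + k]
    E = np.exp(-times[:, None] / t2[None, :])  # (n_echo, 3)
    model = E @ a
    total = a.sum()
    total = total if total > 1e-30 else 1e-30
    f = a / total
    res = np.concatenate([model - signal, sqrt_lam * (f - prior)])

    n_echo = times.size
    jac = np.zeros((n_echo + 3, params.size))
    jac[:n_echo, :3] = E
    # d f_i / d a_j = (delta_ij * total - a_i) / total^2
    jac[n_echo:, :3] = sqrt_lam * (np.eye(3) * total - a[:, None]) / total**2
    for k, pool in enumerate(free_pools):
        i = _POOLS.index(pool)
        jac[:n_echo, 3 + k] = a[i] * (times / t2[i] ** 2) * E[:, i]
    return res, jac


_START_FRACTIONS = (
    None,  # placeholder: the model prior
    (0.05, 0.75, 0.20),  # CSF-heavy
    (0.30, 0.65, 0.05),  # MW-heavy
)


def fit_voxel(signal, times_ms, model: T2PoolModel | None = None) -> VoxelFit:
    """Bounded nonlinear least squares for one voxel, with three deterministic
    multi-starts (prior, CSF-heavy, MW-heavy); ties broken by lowest objective
    then lexicographic parameter order.

    An all-zero signal is flagged as a fit failure carrying the prior
    fractions; non-finite input raises.
    """
    model = model or T2PoolModel()
    signal = np.asarray(signal, float)
    times = np.asarray(times_ms, float)
    if signal.size != times.size or signal.size < 4:
        raise ValueError("need matching signal/times vectors with >= 4 echoes")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains non-finite values")
    t2_init = np.array([model.t2_init_ms[p] for p in _POOLS])
    if not np.any(signal > 0):
        return VoxelFit(*model.f_prior, *t2_init, m0=0.0, objective=0.0, converged=False)

    lam = model.effective_lambda(signal)
    sqrt_lam = np.sqrt(lam)
    prior = np.asarray(model.f_prior, float)
    free_pools = _free_t2_pools(model)
    lo = np.concatenate([np.zeros(3), [model.t2_bounds_ms[p][0] for p in free_pools]])
    hi = np.concatenate([np.full(3, np.inf), [model.t2_bounds_ms[p][1] for p in free_pools]])

    m0_est = float(signal[0])
    best = None
    for start_f in _START_FRACTIONS:
        f0 = prior if start_f is None else np.asarray(start_f, float)
        x0 = np.concatenate([m0_est * f0, [model.t2_init_ms[p] for p in free_pools]])
        x0 = np.clip(x0, lo, hi + 0.0)
        res = least_squares(
            lambda x: _residuals_and_jac(x, times, signal, t2_init, free_pools, sqrt_lam, prior)[0],
            x0,
            jac=lambda x: _residuals_and_jac(x, times, signal, t2_init, free_pools, sqrt_lam, prior)[1],
            bounds=(lo, hi),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=200,
        )
        obj = float(np.sum(res.fun**2))
        key = (obj, tuple(res.x))
        if best is None or key < best[0]:
            best = (key, res)

    res = best[1]
    a = res.x[:3]
    total = a.sum()
    if total <= 0:
        return VoxelFit(*model.f_prior, *t2_init, m0=0.0, objective=float(np.sum(res.fun**2)),
                        converged=False)
    f = a / total
    t2 = t2_init.copy()
    for k, pool in enumerate(free_pools):
        t2[_POOLS.index(pool)] = res.x[3 + k]
    return VoxelFit(
        f_mw=float(f[0]), f_ie=float(f[1]), f_csf=float(f[2]),
        t2_mw=float(t2[0]), t2_ie=float(t2[1]), t2_csf=float(t2[2]),
        m0=float(total), objective=float(np.sum(res.fun**2)),
        converged=bool(res.success),
    )


def grid_search_simplex(signal, times_ms, t2_ms, step: float = 0.005,
                        lam: float = 0.0, f_prior=(0.10, 0.85, 0.05)):
    """Exhaustive search over the fraction simplex at fixed T2s.

    For each grid point the optimal M0 has the closed form <g, S>/<g, g> with
    g the unit-amplitude decay profile.  Returns (fractions, m0, objective).
    Independent of the least-squares path; used as its oracle.
    """
    signal = np.asarray(signal, float)
    times = np.asarray(times_ms, float)
    t2 = np.asarray(t2_ms, float)
    prior = np.asarray(f_prior, float)
    E = np.exp(-times[:, None] / t2[None, :])

    vals = np.arange(0.0, 1.0 + step / 2, step)
    f_mw, f_csf = np.meshgrid(vals, vals, indexing="ij")
    f_mw, f_csf = f_mw.ravel(), f_csf.ravel()
    f_ie = 1.0 - f_mw - f_csf
    ok = f_ie >= -1e-12
    F = np.stack([f_mw[ok], np.clip(f_ie[ok], 0, None), f_csf[ok]], axis=1)  # (G, 3)

    g = F @ E.T  # (G, n_echo)
    gg = np.sum(g * g, axis=1)
    gs = g @ signal
    m0 = np.where(gg > 0, gs / np.maximum(gg, 1e-30), 0.0)
    resid = m0[:, None] * g - signal[None, :]
    obj = np.sum(resid**2, axis=1) + lam * np.sum((F - prior) ** 2, axis=1)
    i = int(np.argmin(obj))
    return F[i], float(m0[i]), float(obj[i])


def fit_volume(series, model: T2PoolModel | None = None) -> RelaxometryMaps:
    """Voxelwise independent application of :func:`fit_voxel` inside the brain
    mask.  Outside the mask all maps are zero; non-converged voxels carry the
    prior fractions and are recorded in the failure mask."""
    model = model or T2PoolModel()
    data = np.asarray(series.data, float)
    mask = np.asarray(series.brain_mask, bool)
    times = np.asarray(series.t2prep_times_ms, float)
    if data.shape[-1] != times.size:
        raise ValueError("echo dimension does not match the echo-time list")
    if not mask.any():
        raise ValueError("brain mask is empty")

    shape = data.shape[:-1]
    maps = {k: np.zeros(shape) for k in
            ("f_mw", "f_ie", "f_csf", "t2_mw", "t2_ie", "t2_csf", "m0", "objective")}
    failure = np.zeros(shape, dtype=bool)
    for idx in np.argwhere(mask):
        vf = fit_voxel(data[tuple(idx)], times, model)
        tix = tuple(idx)
        for k in maps:
            maps[k][tix] = getattr(vf, k)
        failure[tix] = not vf.converged
    return RelaxometryMaps(**maps, failure_mask=failure, brain_mask=mask.copy())
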