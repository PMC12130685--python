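"""Synthetic brain phantoms, acquisitions, and cohorts.

Every downstream stage of the glymphatic-fluid mapping pipeline (relaxometry,
free-water DTI, PVS morphometry, quantification, statistics) is testable on the
objects generated here without any external data.  The geometry is a
concentric-shell brain -- a grey-matter rind over a white-matter core over a
ventricular CSF centre -- with straight-cylinder perivascular-space (PVS)
tubules and small white-matter-hyperintensity (WMH) blobs embedded in WM, so
that volumes and burdens have analytic ground truth.

Noise follows magnitude-MRI physics: Rician for the multi-echo T2 and diffusion
series (sigma tied to the signal at t = 0 / b = 0 through the requested SNR),
Gaussian for structural and PET volumes.  All modalities share one 1 mm
isotropic RAS grid with an identity affine; inter-modality registration is the
identity by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionSpec",
    "PhantomSpec",
    "Phantom",
    "ContrastSpec",
    "CohortSpec",
    "SubjectRecord",
    "MultiEchoSeries",
    "DwiSeries",
    "fibonacci_directions",
    "default_acquisition",
    "make_phantom",
    "add_rician_noise",
    "simulate_multiecho",
    "simulate_dwi",
    "simulate_structural",
    "simulate_pet",
    "make_subject_phantom",
    "iter_cohort",
    "make_cohort",
]

# T2prep times of the FAST-T2 protocol (ms); t = 0 means T2-prep off.
FAST_T2_TIMES_MS = (0.0, 7.5, 17.5, 67.5, 147.5, 307.5)
# Two-shell diffusion protocol: b-values in s/mm^2.
DWI_SHELLS = (1500.0, 3000.0)


class IdentifiabilityError(ValueError):
    """Raised when an acquisition cannot support the requested model fit."""


def fibonacci_directions(n: int) -> np.ndarray:
    """``n`` roughly uniform unit vectors on the upper hemisphere (golden-angle
    spiral).  Deterministic; adequate for a synthetic two-shell scheme."""
    i = np.arange(n, dtype=float)
    z = (i + 0.5) / n
    phi = 2.0 * np.pi * i * (1.0 - 1.0 / ((1.0 + np.sqrt(5.0)) / 2.0))
    r = np.sqrt(1.0 - z**2)
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition timing/encoding shared by the simulators.

    ``t2prep_times_ms`` must be strictly increasing and start at 0;
    every nonzero-b gradient direction must have unit norm.
    """

    t2prep_times_ms: tuple[float, ...] = FAST_T2_TIMES_MS
    bvals: tuple[float, ...] = ()
    bvecs: tuple[tuple[float, float, float], ...] = ()
    voxel_size_mm: float = 1.0

    def __post_init__(self):
        t = np.asarray(self.t2prep_times_ms, float)
        if t.size == 0 or t[0] != 0.0:
            raise ValueError("t2prep_times_ms must start at 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t2prep_times_ms must be strictly increasing")
        b = np.asarray(self.bvals, float)
        g = np.asarray(self.bvecs, float).reshape(-1, 3) if self.bvecs else np.zeros((0, 3))
        if b.size != g.shape[0]:
            raise ValueError("len(bvals) must equal len(bvecs)")
        nz = b > 0
        if nz.any():
            norms = np.linalg.norm(g[nz], axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-6):
                raise ValueError("nonzero-b directions must have unit norm")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.t2prep_times_ms, float)

    @property
    def bvals_arr(self) -> np.ndarray:
        return np.asarray(self.bvals, float)

    @property
    def bvecs_arr(self) -> np.ndarray:
        return np.asarray(self.bvecs, float).reshape(-1, 3)

    def n_shells(self) -> int:
        return len(set(np.round(self.bvals_arr[self.bvals_arr > 0], 3)))


def default_acquisition(n_b0: int = 6, n_dirs_per_shell: int = 49) -> AcquisitionSpec:
    """Protocol matching the study acquisition: T2prep times
    {0, 7.5, 17.5, 67.5, 147.5, 307.5} ms and a two-shell DWI scheme
    (b = 1500, 3000 s/mm^2, 49 + 49 = 98 diffusion directions)."""
    dirs = fibonacci_directions(n_dirs_per_shell)
    bvals = [0.0] * n_b0
    bvecs = [(0.0, 0.0, 0.0)] * n_b0
    for b in DWI_SHELLS:
        bvals += [b] * n_dirs_per_shell
        bvecs += [tuple(d) for d in dirs]
    return AcquisitionSpec(bvals=tuple(bvals), bvecs=tuple(bvecs))


@dataclass(frozen=True)
class PvsTubule:
    """Straight cylinder along ``axis`` (0/1/2), centred on the mid-plane,
    offset from the grid centre in the two transverse coordinates."""

    axis: int = 0
    offset: tuple[float, float] = (0.0, 7.0)  # transverse offsets (voxels)
    radius_vox: float = 1.0
    length_vox: int = 10


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the concentric-shell phantom.

    Radii are fractions of the half-extent of the smallest grid dimension.
    Water-compartment fractions are (myelin water, intra/extra-cellular, CSF)
    and must sum to 1 per tissue.
    """

    r_ventricle: float = 0.25
    r_wm: float = 0.70
    r_gm: float = 0.85
    fractions_wm: tuple[float, float, float] = (0.12, 0.83, 0.05)
    fractions_gm: tuple[float, float, float] = (0.03, 0.92, 0.05)
    t2_ms: tuple[float, float, float] = (20.0, 80.0, 2000.0)
    # tissue diffusion tensors (mm^2/s): WM prolate along x, GM isotropic
    wm_eigs: tuple[float, float, float] = (1.5e-3, 0.4e-3, 0.4e-3)
    gm_md: float = 0.8e-3
    fw_wm: float = 0.36
    fw_gm: float = 0.30
    wmh_fcsf: float = 0.10
    wmh_fw: float = 0.50
    wmh_radius_vox: float = 2.0
    tubules: tuple[PvsTubule, ...] = (PvsTubule(),)
    fraction_jitter_sd: float = 0.0  # optional spatial jitter on f_csf


@dataclass
class Phantom:
    """Synthetic brain with per-voxel ground truth for every pipeline stage."""

    shape: tuple[int, int, int]
    labels: np.ndarray  # 0 background, 1 GM, 2 WM, 3 ventricular CSF
    masks: dict[str, np.ndarray]  # gm, wm, wmh, pvs_truth, admask, cerebellum_ref
    fractions: dict[str, np.ndarray]  # f_mw, f_ie, f_csf
    tissue_tensor: np.ndarray  # (..., 3, 3) mm^2/s
    fw_truth: np.ndarray
    m0: np.ndarray
    t2_ms: tuple[float, float, float]
    seed: int
    voxel_size_mm: float = 1.0

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0


def _radial_distance(shape: tuple[int, int, int]) -> np.ndarray:
    c = [(s - 1) / 2.0 for s in shape]
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    return np.sqrt(sum((g - ci) ** 2 for g, ci in zip(grids, c)))


def tubule_voxels(shape: tuple[int, int, int], tub: PvsTubule) -> np.ndarray:
    """Integer voxel coordinates of the analytic cylinder, ordered along the
    axis then by transverse offset.  Serves as its own brute-force oracle:
    the scan is an exhaustive test of every grid voxel against the cylinder."""
    c = [(s - 1) / 2.0 for s in shape]
    ax = tub.axis
    tr = [i for i in range(3) if i != ax]
    lo = int(np.floor(c[ax] - tub.length_vox / 2.0 + 0.5))
    coords = []
    for a in range(lo, lo + tub.length_vox):
        for u in range(shape[tr[0]]):
            for v in range(shape[tr[1]]):
                du = u - (c[tr[0]] + tub.offset[0])
                dv = v - (c[tr[1]] + tub.offset[1])
                if du * du + dv * dv <= tub.radius_vox**2 + 1e-12:
                    vox = [0, 0, 0]
                    vox[ax], vox[tr[0]], vox[tr[1]] = a, u, v
                    coords.append(vox)
    return np.asarray(coords, dtype=int).reshape(-1, 3)


def make_phantom(
    shape: tuple[int, int, int] = (32, 32, 32),
    spec: PhantomSpec | None = None,
    seed: int = 0,
) -> Phantom:
    """Build the concentric-shell phantom with embedded PVS tubules and a WMH
    blob.  Deterministic given ``seed`` (the seed only drives the optional
    f_csf jitter)."""
    spec = spec or PhantomSpec()
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 16:
        raise ValueError(f"degenerate shape {shape}: each dimension must be >= 16")
    for f3 in (spec.fractions_wm, spec.fractions_gm):
        arr = np.asarray(f3, float)
        if np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError("tissue fractions must be nonnegative and sum to 1")

    half = min(shape) / 2.0 - 1.0
    r = _radial_distance(shape)
    r_vent, r_wm, r_gm = (spec.r_ventricle * half, spec.r_wm * half, spec.r_gm * half)
    wm_thickness = r_wm - r_vent
    labels = np.zeros(shape, dtype=np.int16)
    labels[r <= r_gm] = 1
    labels[r <= r_wm] = 2
    labels[r <= r_vent] = 3

    gm = labels == 1
    wm = labels == 2
    csf = labels == 3
    brain = labels > 0

    for tub in spec.tubules:
        if tub.radius_vox >= wm_thickness:
            raise ValueError(
                f"tubule radius {tub.radius_vox} exceeds WM shell thickness {wm_thickness:.1f}"
            )

    pvs = np.zeros(shape, dtype=bool)
    for tub in spec.tubules:
        vox = tubule_voxels(shape, tub)
        if vox.size:
            pvs[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    pvs &= wm

    # WMH: small sphere in WM, diametrically opposite the default tubule
    c = np.array([(s - 1) / 2.0 for s in shape])
    wmh_centre = c + np.array([0.0, 0.0, -0.5 * (r_vent + r_wm)])
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    d_wmh = np.sqrt(sum((g - ci) ** 2 for g, ci in zip(grids, wmh_centre)))
    wmh = (d_wmh <= spec.wmh_radius_vox) & wm & ~pvs

    z = grids[2]
    admask = gm & (z - c[2] > 0.62 * r_gm)
    cereb = gm & (c[2] - z > 0.62 * r_gm)

    rng = np.random.default_rng(seed)
    f_mw = np.zeros(shape)
    f_ie = np.zeros(shape)
    f_csf = np.zeros(shape)
    for mask, (a, b, cc) in ((wm, spec.fractions_wm), (gm, spec.fractions_gm)):
        f_mw[mask], f_ie[mask], f_csf[mask] = a, b, cc
    f_csf[csf] = 1.0
    f_csf[wmh] = spec.wmh_fcsf
    if spec.fraction_jitter_sd > 0:
        tissue = gm | wm
        jit = rng.normal(0.0, spec.fraction_jitter_sd, size=shape)
        f_csf[tissue] = np.clip(f_csf[tissue] + jit[tissue], 0.0, 0.5)
    f_ie[brain] = 1.0 - f_mw[brain] - f_csf[brain]

    tensor = np.zeros(shape + (3, 3))
    iso = np.eye(3)
    tensor[gm] = spec.gm_md * iso
    tensor[csf] = 3.0e-3 * iso
    tensor[wm] = np.diag(spec.wm_eigs)

    fw = np.zeros(shape)
    fw[wm] = spec.fw_wm
    fw[gm] = spec.fw_gm
    fw[csf] = 1.0
    fw[wmh] = spec.wmh_fw

    m0 = np.zeros(shape)
    m0[brain] = 1.0

    return Phantom(
        shape=shape,
        labels=labels,
        masks={
            "gm": gm,
            "wm": wm,
            "wmh": wmh,
            "pvs_truth": pvs,
            "admask": admask,
            "cerebellum_ref": cereb,
        },
        fractions={"f_mw": f_mw, "f_ie": f_ie, "f_csf": f_csf},
        tissue_tensor=tensor,
        fw_truth=fw,
        m0=m0,
        t2_ms=spec.t2_ms,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# forward simulators
# ---------------------------------------------------------------------------


@dataclass
class MultiEchoSeries:
    data: np.ndarray  # (x, y, z, echo), magnitude
    t2prep_times_ms: np.ndarray
    brain_mask: np.ndarray

    def __post_init__(self):
        if self.data.shape[-1] != len(self.t2prep_times_ms):
            raise ValueError("echo dimension does not match the echo-time list")


@dataclass
class DwiSeries:
    data: np.ndarray  # (x, y, z, volume)
    bvals: np.ndarray
    bvecs: np.ndarray
    brain_mask: np.ndarray


def add_rician_noise(signal: np.ndarray, sigma, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of (signal + n1) + i n2 with n ~ N(0, sigma).  At zero signal
    the mean is sigma * sqrt(pi/2) (the Rician noise floor)."""
    sigma = np.asarray(sigma, float)
    n1 = rng.normal(size=signal.shape)
    n2 = rng.normal(size=signal.shape)
    return np.sqrt((signal + sigma * n1) ** 2 + (sigma * n2) ** 2)


def _multiecho_clean(phantom: Phantom, times: np.ndarray) -> np.ndarray:
    t2 = np.asarray(phantom.t2_ms, float)
    decay = np.exp(-times[None, :] / t2[:, None])  # (3, n_echo)
    f = np.stack(
        [phantom.fractions["f_mw"], phantom.fractions["f_ie"], phantom.fractions["f_csf"]],
        axis=-1,
    )
    return phantom.m0[..., None] * (f @ decay)


def simulate_multiecho(
    phantom: Phantom,
    acq: AcquisitionSpec | None = None,
    snr: float = np.inf,
    seed: int = 0,
) -> MultiEchoSeries:
    """Three-exponential T2prep decay per voxel; Rician noise with
    sigma = S(t=0)/snr per voxel, exact forward model at snr = inf."""
    acq = acq or AcquisitionSpec()
    times = acq.times
    if times.size < 4:
        raise ValueError("need at least 4 echo times")
    if not snr > 0:
        raise ValueError("snr must be positive")
    for key in ("f_mw", "f_ie", "f_csf"):
        if key not in phantom.fractions:
            raise ValueError(f"phantom is missing fraction field {key!r}")
    clean = _multiecho_clean(phantom, times)
    if np.isinf(snr):
        data = clean
    else:
        rng = np.random.default_rng(seed)
        sigma = (phantom.m0 / snr)[..., None]
        data = add_rician_noise(clean, sigma, rng)
    return MultiEchoSeries(data=data, t2prep_times_ms=times, brain_mask=phantom.brain_mask.copy())


def bitensor_forward(
    d_tissue: np.ndarray,
    f_fw: np.ndarray,
    s0: np.ndarray,
    bvals: np.ndarray,
    bvecs: np.ndarray,
    d_iso: float = 3.0e-3,
) -> np.ndarray:
    """Vectorized bi-tensor signal S = S0[(1-f) e^{-b g'Dg} + f e^{-b d_iso}]
    for per-voxel tensors (broadcast over leading axes)."""
    q = np.einsum("vi,...ij,vj->...v", bvecs, d_tissue, bvecs)
    tissue = np.exp(-bvals * q)
    water = np.exp(-bvals * d_iso)
    return s0[..., None] * ((1.0 - f_fw[..., None]) * tissue + f_fw[..., None] * water)


def simulate_dwi(
    phantom: Phantom,
    acq: AcquisitionSpec | None = None,
    snr: float = np.inf,
    seed: int = 0,
    d_iso: float = 3.0e-3,
) -> DwiSeries:
    """Two-shell bi-tensor DWI.  Refuses single-shell schemes: the free-water
    fraction and mean tissue diffusivity are not jointly identifiable from one
    shell."""
    acq = acq or default_acquisition()
    bvals, bvecs = acq.bvals_arr, acq.bvecs_arr
    if acq.n_shells() < 2:
        raise IdentifiabilityError("bi-tensor simulation/fitting requires >= 2 nonzero shells")
    nz = bvals > 0
    if len({tuple(np.round(v, 6)) for v in bvecs[nz]}) < 6:
        raise ValueError("need >= 6 unique nonzero gradient directions")
    clean = bitensor_forward(
        phantom.tissue_tensor, phantom.fw_truth, phantom.m0, bvals, bvecs, d_iso
    )
    if np.isinf(snr):
        data = clean
    else:
        rng = np.random.default_rng(seed)
        sigma = (phantom.m0 / snr)[..., None]
        data = add_rician_noise(clean, sigma, rng)
    return DwiSeries(data=data, bvals=bvals, bvecs=bvecs, brain_mask=phantom.brain_mask.copy())


@dataclass(frozen=True)
class ContrastSpec:
    """Per-tissue structural intensities.  Defaults make PVS voxels
    T2w-hyperintense and T1w-hypointense, so the T1w/T2w ratio (EPC) is dark
    inside PVS relative to surrounding WM."""

    t1w: dict[str, float] = field(
        default_factory=lambda: {"gm": 0.70, "wm": 1.00, "csf": 0.20, "pvs": 0.55, "wmh": 0.85}
    )
    t2w: dict[str, float] = field(
        default_factory=lambda: {"gm": 0.70, "wm": 0.50, "csf": 1.00, "pvs": 0.95, "wmh": 0.80}
    )
    noise_sd: float = 0.02


def simulate_structural(
    phantom: Phantom,
    contrast: ContrastSpec | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant T1w/T2w pair with Gaussian noise."""
    contrast = contrast or ContrastSpec()
    for d in (contrast.t1w, contrast.t2w):
        if any(v <= 0 for v in d.values()):
            raise ValueError("structural intensity means must be positive")
    rng = np.random.default_rng(seed)
    vols = []
    regions = (
        ("gm", phantom.masks["gm"]),
        ("wm", phantom.masks["wm"]),
        ("csf", phantom.labels == 3),
        ("wmh", phantom.masks["wmh"]),
        ("pvs", phantom.masks["pvs_truth"]),
    )
    for means in (contrast.t1w, contrast.t2w):
        vol = np.zeros(phantom.shape)
        for name, mask in regions:  # later entries override (wmh/pvs on top of wm)
            vol[mask] = means[name]
        if contrast.noise_sd > 0:
            vol = vol + rng.normal(0.0, contrast.noise_sd, size=vol.shape) * phantom.brain_mask
        vols.append(vol)
    return vols[0], vols[1]


def simulate_pet(
    phantom: Phantom,
    suvr_truth: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Uptake volume whose noise-free mean(admask)/mean(cerebellum_ref) equals
    ``suvr_truth`` exactly; additive Gaussian noise elsewhere."""
    adm = phantom.masks["admask"]
    ref = phantom.masks["cerebellum_ref"]
    if not adm.any() or not ref.any():
        raise ValueError("admask and cerebellum_ref must be nonempty")
    pet = np.zeros(phantom.shape)
    pet[phantom.brain_mask] = 1.0
    pet[adm] = float(suvr_truth)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        pet = pet + rng.normal(0.0, noise_sd, size=pet.shape) * phantom.brain_mask
    return pet


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

# Group biomarker targets (%), means (SD), matching the study's clinical table.
_TABLE1_MEANS = {
    "NL": {"wm_pcsf": 4.45, "gm_pcsf": 4.41, "wm_fw": 25.15, "pvs_wmv": 1.52, "suvr": 1.17},
    "MCIAD": {"wm_pcsf": 4.86, "gm_pcsf": 4.83, "wm_fw": 25.77, "pvs_wmv": 1.68, "suvr": 2.07},
}
_TABLE1_SDS = {
    "NL": {"wm_pcsf": 0.29, "gm_pcsf": 0.31, "wm_fw": 1.26, "pvs_wmv": 0.43, "suvr": 0.13},
    "MCIAD": {"wm_pcsf": 0.34, "gm_pcsf": 0.36, "wm_fw": 0.99, "pvs_wmv": 0.49, "suvr": 0.53},
}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort generator defaults carry the study's group structure: 16 NL and
    13 MCI/AD subjects, group biomarker means/SDs from the clinical table, and
    a planted positive WM pCSF -> amyloid-SUVR association."""

    n_nl: int = 16
    n_mciad: int = 13
    group_means: dict = field(default_factory=lambda: {g: dict(v) for g, v in _TABLE1_MEANS.items()})
    group_sds: dict = field(default_factory=lambda: {g: dict(v) for g, v in _TABLE1_SDS.items()})
    age_mean: dict = field(default_factory=lambda: {"NL": 67.69, "MCIAD": 73.00})
    age_sd: dict = field(default_factory=lambda: {"NL": 8.40, "MCIAD": 8.54})
    sex_prob_male: dict = field(default_factory=lambda: {"NL": 6 / 16, "MCIAD": 5 / 13})
    apoe4_prob: dict = field(default_factory=lambda: {"NL": 3 / 16, "MCIAD": 9 / 13})
    # SUVR increase per percentage point of WM pCSF above the group mean
    slope_pcsf_suvr: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_nl < 2 or self.n_mciad < 2:
            raise ValueError("each diagnostic group needs n >= 2")
        for g in ("NL", "MCIAD"):
            if any(s <= 0 for s in self.group_sds[g].values()):
                raise ValueError("group sds must be positive")
            for p in (self.sex_prob_male[g], self.apoe4_prob[g]):
                if not 0.0 <= p <= 1.0:
                    raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class SubjectRecord:
    id: str
    age: float
    sex: str  # 'F' or 'M'
    dx: str  # 'NL' or 'MCIAD'
    apoe4: int
    wm_pcsf: float  # ground-truth biomarker values, %
    gm_pcsf: float
    wm_fw: float
    pvs_wmv: float
    suvr_truth: float


def _draw_subject(rng: np.random.Generator, spec: CohortSpec, dx: str, idx: int) -> SubjectRecord:
    m, s = spec.group_means[dx], spec.group_sds[dx]
    age = max(40.0, rng.normal(spec.age_mean[dx], spec.age_sd[dx]))
    sex = "M" if rng.random() < spec.sex_prob_male[dx] else "F"
    apoe4 = int(rng.random() < spec.apoe4_prob[dx])
    vals = {k: float(np.clip(rng.normal(m[k], s[k]), 0.05, 99.0)) for k in ("wm_pcsf", "gm_pcsf", "wm_fw", "pvs_wmv")}
    # SUVR correlated with WM pCSF: total SD matches the group target
    resid_sd = np.sqrt(max(s["suvr"] ** 2 - (spec.slope_pcsf_suvr * s["wm_pcsf"]) ** 2, 1e-4))
    suvr = m["suvr"] + spec.slope_pcsf_suvr * (vals["wm_pcsf"] - m["wm_pcsf"]) + rng.normal(0.0, resid_sd)
    suvr = float(np.clip(suvr, 0.5, 5.0))
    return SubjectRecord(id=f"{dx.lower()}{idx:03d}", age=float(age), sex=sex, dx=dx,
                         apoe4=apoe4, suvr_truth=suvr, **vals)


# TWC used to map biomarker %-truths back to compartment fractions
_TWC = {"gm": 0.83, "wm": 0.70}


def make_subject_phantom(base: Phantom, record: SubjectRecord,
                         tubule_pool: np.ndarray | None = None) -> Phantom:
    """Rescale the base phantom's ground-truth fields to a subject's biomarker
    truths.  f_csf is set per tissue so that f_csf * TWC * 100 equals the
    subject's pCSF (%), adjusting f_ie to preserve the unit sum; fw_truth is
    set analogously; the PVS tubule voxel count is set to match the subject's
    PVS/WMV burden against the analytic WM volume."""
    wm, gm = base.masks["wm"], base.masks["gm"]
    f_mw = base.fractions["f_mw"].copy()
    f_csf = base.fractions["f_csf"].copy()
    # WMH voxels keep their elevated base f_csf, so WMH exclusion stays material
    f_csf[wm & ~base.masks["wmh"]] = record.wm_pcsf / 100.0 / _TWC["wm"]
    f_csf[gm] = record.gm_pcsf / 100.0 / _TWC["gm"]
    f_ie = np.zeros_like(f_csf)
    brain = base.brain_mask
    f_ie[brain] = 1.0 - f_mw[brain] - f_csf[brain]

    fw = base.fw_truth.copy()
    fw[wm] = record.wm_fw / 100.0 / _TWC["wm"]

    masks = dict(base.masks)
    if tubule_pool is not None and tubule_pool.size:
        n_target = int(round(record.pvs_wmv / 100.0 * int(wm.sum())))
        n_target = min(max(n_target, 1), tubule_pool.shape[0])
        pvs = np.zeros(base.shape, dtype=bool)
        sel = tubule_pool[:n_target]
        pvs[sel[:, 0], sel[:, 1], sel[:, 2]] = True
        masks["pvs_truth"] = pvs & wm & ~masks["wmh"]

    return dataclasses.replace(
        base,
        masks=masks,
        fractions={"f_mw": f_mw, "f_ie": f_ie, "f_csf": f_csf},
        fw_truth=fw,
    )


def cohort_tubule_pool(shape: tuple[int, int, int]) -> np.ndarray:
    """Candidate PVS voxel coordinates: three parallel tubule sites in the WM
    shell, filled in order, so any burden up to ~3% of WMV is realisable."""
    sites = (
        PvsTubule(axis=0, offset=(0.0, 7.0), radius_vox=1.0, length_vox=14),
        PvsTubule(axis=1, offset=(7.0, 0.0), radius_vox=1.0, length_vox=14),
        PvsTubule(axis=0, offset=(-7.0, 0.0), radius_vox=1.0, length_vox=14),
    )
    return np.concatenate([tubule_voxels(shape, t) for t in sites], axis=0)


def iter_cohort(spec: CohortSpec | None = None, shape: tuple[int, int, int] = (32, 32, 32),
                phantom_spec: PhantomSpec | None = None):
    """Yield (SubjectRecord, Phantom) pairs one at a time.  One master seed
    spawns independent per-subject child streams, so cohorts are reproducible
    and subjects independent."""
    spec = spec or CohortSpec()
    base = make_phantom(shape, phantom_spec, seed=spec.seed)
    pool = cohort_tubule_pool(shape)
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_nl + spec.n_mciad)
    groups = [("NL", i) for i in range(spec.n_nl)] + [("MCIAD", i) for i in range(spec.n_mciad)]
    for (dx, idx), child in zip(groups, children):
        rng = np.random.default_rng(child)
        record = _draw_subject(rng, spec, dx, idx)
        yield record, make_subject_phantom(base, record, pool)


def make_cohort(spec: CohortSpec | None = None, shape: tuple[int, int, int] = (32, 32, 32),
                phantom_spec: PhantomSpec | None = None) -> list[tuple[SubjectRecord, Phantom]]:
    return list(iter_cohort(spec, shape, phantom_spec))
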