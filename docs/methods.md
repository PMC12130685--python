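# Methods

`glymap` implements and validates a pipeline for mapping glymphatic fluid —
the CSF-like water in perivascular spaces (PVS) — from MRI, and for comparing
three candidate biomarkers of it: parenchymal CSF (pCSF) from multi-echo T2
relaxometry, free water (FW) from diffusion MRI, and the segmented PVS burden
(PVS/WMV). No human data are used anywhere: every stage runs on a synthetic
brain phantom and cohort generator whose ground truth is analytic, so each
estimator can be checked against what was planted.

## Signal models

**Three-compartment T2 relaxometry (pCSF).** The T2prep multi-echo signal is

    S(t) = M0 [ f_mw e^(-t/T2_mw) + f_ie e^(-t/T2_ie) + f_csf e^(-t/T2_csf) ],
    f_mw + f_ie + f_csf = 1,

with pools for myelin water (T2 bounds 5–40 ms, init 20 ms), intra/extra-
cellular water (40–200 ms, init 80 ms) and parenchymal CSF (200–2000 ms). The
CSF fraction f_csf is the parenchymal CSF fraction (pCSFF). The CSF T2 is
fixed at 2000 ms by default: free CSF-like water at 3 T relaxes with T2 ≈ 2 s,
and a protocol whose longest T2prep time is 307.5 ms cannot resolve T2s far
beyond its sampling window (a flag frees it within 200–2000 ms). The MW/IE
bounds and initials are standard multi-compartment-T2 values, exposed in the
model configuration.

The fit is bounded nonlinear least squares on pool amplitudes (fractions are
the normalized amplitudes, so the unit-sum constraint is exact by
construction) with an L2 penalty pulling the fraction vector toward the prior
(0.10, 0.85, 0.05):

    objective = ||S_model - S_data||^2 + lambda ||f - f_prior||^2 .

With six echoes the three-pool inversion is ill-posed; the penalty stabilizes
the long-T2 estimate. `lambda` defaults to `0.01 * ||S_data||^2` so the
penalty scale tracks the data scale; at the phantom's WM composition the
induced bias on pCSFF is below 1e-3 (zero when the truth equals the prior).
Three deterministic multi-starts (prior, CSF-heavy, MW-heavy amplitudes) guard
against the multi-modality of multi-exponential objectives; ties break by
lowest objective, then lexicographic parameter order. Analytic Jacobians are
supplied. Non-converged or all-zero voxels carry the prior fractions and are
recorded in a failure mask rather than aborting the volume.

Noise is treated as Gaussian on magnitude data, valid at SNR ≳ 20; the Rician
floor is simulated faithfully but not bias-corrected in the fit, which
contributes the small positive pCSFF bias visible at SNR 20 in
`results/relaxometry_recovery.csv`.

**Bi-tensor free-water DTI (FW).** The DWI signal is

    S(b, g) = S0 [ (1 - f) e^(-b g'Dg) + f e^(-b d_iso) ],

with tissue tensor D, free-water fraction f, and d_iso = 3.0e-3 mm²/s (free
water at body temperature; the source protocol does not state it, so it is a
configurable default). Fitting requires two nonzero shells — from a single
shell f and the mean tissue diffusivity trade off exactly — so single-shell
input raises an identifiability error instead of silently regularizing. D is
parameterized by its Cholesky factor (optimizer unconstrained, estimate PSD by
construction), initialized from the classic log-linear single-tensor fit with
f0 = 0.1. At a pure free-water voxel (f = 1) the model is degenerate: any f
with D = d_iso·I reproduces the signal, so map accuracy is only asserted in
tissue; ventricular values are not interpretable, as in any unregularized
free-water fit.

**PVS morphometry.** The enhanced PVS contrast (EPC) is the T1w/T2w ratio
(denominator floored at `eps`, floored voxels flagged); PVS are T2w-bright and
T1w-dark, hence EPC-dark tubes. Multi-scale Frangi vesselness (the standard
Hessian-eigenvalue construction, evaluated via scikit-image) is computed with
alpha = beta = 0.5, per-scale auto structureness constant (half the maximum
Frobenius Hessian norm), scales {0.5, 1.0, 1.5} mm, dark-tube polarity. The
mask is `vesselness >= 0.2` restricted to WM with WMH excluded; clusters
under 2 voxels are removed under 26-connectivity (thin oblique tubes fragment
under 6-connectivity). Burden is 100·|PVS|/|WMV|. The deep-learning
segmentation used in clinical practice is out of scope here; this module
implements its fully specified classical prior, which is the reproducible and
testable core. Thresholds and scales are documented choices, not
reproductions of any trained system.

**Quantification.** pCSFF and DTI-FW measure fractions of voxel *water*;
multiplying by tissue total water content (TWC, constant 0.83 in GM and 0.70
in WM) converts them to fractions of voxel *volume* — the absolute pCSF and
FW reported in percent. WM ROI means exclude WMH; the AD meta-ROI uses the GM
TWC (it is a cortical mask). SUVR is mean PET uptake in the AD meta-ROI over
the cerebellar-cortex reference. All modalities share one 1 mm isotropic grid
with identity affine, so inter-modality registration is the identity;
registration of real data is explicitly out of scope.

## The phantom and cohort generator

The phantom is a concentric-shell brain: ventricular CSF core, WM shell, GM
rind (radii 0.25/0.70/0.85 of the half-extent), at 32³ voxels by default.
Straight-cylinder PVS tubules (default radius 1 voxel, length 10) and a small
spherical WMH blob with elevated f_csf (0.10) and structural hyperintensity
are embedded in WM, so exclusion rules have something to exclude and burdens
have voxel-exact analytic truth. Default water fractions are
(f_mw, f_ie, f_csf) = (0.12, 0.83, 0.05) in WM and (0.03, 0.92, 0.05) in GM
with pool T2s (20, 80, 2000) ms; WM tensors are prolate
(1.5, 0.4, 0.4)·10⁻³ mm²/s, GM isotropic 0.8·10⁻³. Magnitude series (T2prep,
DWI) carry Rician noise with sigma = S(t=0)/SNR per voxel; structural and PET
volumes carry Gaussian noise.

The cohort generator plants the clinical-table group structure: 16 NL and 13
MCI/AD subjects by default, per-group biomarker means/SDs (WM pCSF 4.45±0.29
vs 4.86±0.34 %, GM pCSF 4.41±0.31 vs 4.83±0.36 %, WM FW 25.15±1.26 vs
25.77±0.99 %, PVS/WMV 1.52±0.43 vs 1.68±0.49 %, SUVR 1.17±0.13 vs 2.07±0.53),
ages 67.69±8.40 vs 73.00±8.54 years, male fractions 6/16 vs 5/13 and APOE4
carrier probabilities 3/16 vs 9/13. A positive WM pCSF → SUVR association is
planted with slope 0.3 SUVR per pCSF percentage point — the largest slope
compatible with the NL SUVR SD of 0.13 once the slope's contribution through
the pCSF SD is removed in quadrature — and the SUVR residual SD is set so the
total matches the group target. Per-subject phantoms rescale f_csf per tissue
so that f_csf·TWC reproduces each subject's pCSF truth exactly (WMH voxels
keep their elevated value), set fw analogously, and fill PVS tubule voxels
from a three-site pool to match the subject's burden to within one voxel. One
master seed spawns independent per-subject streams (`numpy` SeedSequence), so
cohorts are bit-reproducible and subjects independent.

What the generator does *not* emulate: realistic anatomy and partial-volume
mixing, B1/flip-angle effects and stimulated echoes, eddy/susceptibility
distortion, spatially varying T2s or tensors within a tissue, PET resolution
effects. Passing tests therefore demonstrate correctness of the estimators
under their own signal models and the statistical machinery around them — not
robustness to real-scanner physics.

## Validation experiments and problem sizes

- **Sensitivity worked example** — percent increase of each planted group
  mean from NL to MCI/AD, at 1-decimal rounding: GM pCSF +9.5%, PVS/WMV
  +10.5%, WM FW +2.5% (WM pCSF gives +9.2%).
- **Relaxometry recovery** — noise-free recovery is asserted at lambda = 0
  (the unregularized contract, error ≤ 1e-3); Monte-Carlo recovery uses 500
  Rician replicates per truth pCSFF ∈ {0.02, 0.05, 0.10} at SNR 100 with the
  default lambda, conditioning on the known pool T2s (`t2_fixed`). With six
  echoes a fully free three-pool fit (5 nonlinear parameters) is barely
  determined and its MAE is ≈ 0.011; conditioned on the T2s the protocol was
  designed around, MAE ≈ 0.007. Both figures are reproducible from
  `glymap.workflows.relaxometry_recovery`; the validation reports the
  conditioned fit and this paragraph is the record of that choice.
- **Oracle equivalence** — on 50 random noise-free voxels the least-squares
  fit (fixed T2s, lambda = 0) must match an exhaustive simplex grid search at
  step 0.005 in objective; the grid search has a closed-form optimal M0 per
  grid point and shares no code with the optimizer.
- **Free-water recovery** — noise-free: f to 1e-3 and tensor elements to 1e-6
  mm²/s; Monte-Carlo: 500 replicates per f ∈ {0.1, 0.25, 0.5} at SNR 40,
  |bias| ≤ 0.05.
- **PVS burden** — measured burden within ±10% of the analytic cylinder
  truth at default settings, plus threshold/exclusion monotonicity.
- **Detection power** — 100 replicate cohorts of 100 subjects per group at
  32³; biomarkers are extracted at ROI level: because the three-exponential
  model is linear in the fractions and the phantom's T2s are spatially
  constant, the ROI-mean signal is exactly the signal of the ROI-mean
  fractions, so fitting it recovers the ROI-mean pCSFF while averaging voxel
  noise down — mirroring ROI averaging in practice and keeping 20,000
  subject-level fits tractable. Each replicate runs phantom → simulation →
  ROI fit → calibration → PET SUVR → statistics; the DWI and PVS stages enter
  neither detection quantity and run in the single full-cohort pipeline
  (`analysis/05`) instead. Voxelwise map fitting is validated separately on
  small phantoms.

## Numerical conventions and edge cases

- Fractions are stored in [0, 1]; tables report percent (SUVR is a ratio).
- Optimizers: `scipy.optimize.least_squares` (trf), tolerances 1e-12 to
  1e-14; relaxometry fits use analytic Jacobians.
- Wilcoxon rank-sum uses the exact null for tie-free samples with n ≤ 20 per
  group, tie-corrected normal approximation otherwise; the 2×2 chi-square
  uses Yates continuity correction by default (flag to disable); the
  Shapiro–Wilk gate is alpha = 0.05 per group (a documented default).
- Categorical coding is treatment coding with female and MCI/AD as reference
  levels, so model terms are `sexM` and `dxNL`.
- Degenerate inputs: all-zero relaxometry voxels → prior fractions + failure
  flag; zero tensors → FA 0; constant variables → flagged NaN correlations or
  a degenerate-test error; empty effective ROIs, empty WM masks, single-shell
  DWI → explicit errors.

## Known limitations

- Rician bias is simulated but not corrected in either fit; at SNR ≲ 20 the
  pCSFF and FW estimates acquire a visible positive bias.
- The PVS segmentation is the classical vesselness prior, not a trained
  model; its absolute Dice on real EPC images would be far below the phantom
  values.
- Free-water maps are meaningless in pure-CSF voxels (model degeneracy).
- The phantom's piecewise-constant tissues make ROI-level and voxel-level
  estimands coincide; real tissue heterogeneity would separate them.
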