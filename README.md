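# glymap

Glymphatic-fluid MRI mapping on synthetic brain phantoms: three-compartment
T2 relaxometry (parenchymal CSF), bi-tensor free-water DTI, Frangi-based
perivascular-space morphometry, total-water-content calibration with ROI/SUVR
quantification, and the comparative cohort statistics — implemented as a
tested library with numbered analysis drivers.

## The problem

The glymphatic system clears metabolic waste (including beta-amyloid) from
brain parenchyma through perivascular spaces (PVS). Three MRI measures
compete as biomarkers of the fluid in that pathway:

- **pCSF** — from a multi-echo T2prep series, the voxel signal is fit as
  three water pools, `S(t) = M0 [f_mw e^(-t/T2_mw) + f_ie e^(-t/T2_ie) +
  f_csf e^(-t/T2_csf)]`; the long-T2 (200–2000 ms) fraction `f_csf` is the
  parenchymal CSF fraction, converted to an absolute volume fraction by the
  tissue total water content (83% GM, 70% WM).
- **FW** — the bi-tensor free-water model
  `S = S0 [(1-f) e^(-b g'Dg) + f e^(-b d_iso)]` on two-shell DWI; `f` is the
  isotropic free-water fraction, calibrated the same way.
- **PVS/WMV** — PVS segmented on the T1w/T2w ratio (EPC) by multi-scale
  Frangi vesselness, restricted to white matter with WMH excluded, as a
  percentage of WM volume.

Because no public dataset accompanies this problem, the package ships a
phantom and cohort generator with analytic ground truth for every stage, and
validates the whole chain — forward models, fits, segmentation, calibration,
statistics — against what was planted.

## Worked example

```python
from glymap import phantom as ph, stats, workflows

# percent increase of each planted group mean, NL -> MCI/AD
print(workflows.sensitivity_summary().to_string(index=False))

# a full 29-subject cohort, measured end to end
table = workflows.run_cohort_pipeline(ph.CohortSpec(seed=42))
print(stats.group_compare(table, "wm_pcsf", kind="auto"))
```

prints

```
biomarker  mean_nl  mean_mciad  percent_increase
  wm_pcsf     4.45        4.86               9.2
  gm_pcsf     4.41        4.83               9.5
    wm_fw    25.15       25.77               2.5
  pvs_wmv     1.52        1.68              10.5
     suvr     1.17        2.07              76.9
GroupComparison(test='t_test', statistic=3.890..., pvalue=0.00059...)
```

The sensitivity table is the headline comparison: going from cognitively
normal to MCI/AD, pCSF rises ~9.5% and PVS burden 10.5%, while free water
rises only ~2.5% — pCSF is the more disease-sensitive fluid measure. The
group comparison shows the pipeline recovering the planted WM pCSF difference
from simulated images (the t-test was selected by the Shapiro–Wilk gate).

## Analysis scripts

Each driver under `analysis/` is a thin narrative over the library and writes
its tables to `results/`:

| script | what it does |
| --- | --- |
| `01_group_sensitivity.py` | percent-increase sensitivity table from the planted group means |
| `02_relaxometry_recovery.py` | Monte-Carlo pCSFF recovery across SNR |
| `03_freewater_recovery.py` | noise-free and SNR-40 free-water recovery |
| `04_pvs_burden.py` | analytic-cylinder burden recovery and threshold sweep |
| `05_cohort_pipeline.py` | full 29-subject cohort: simulate → fit → quantify → statistics |
| `06_detection_power.py` | detection rates of the planted effects over 100 replicate cohorts |

A `glymap` CLI exposes the per-stage tools (`glymap simulate`, `fit-t2`,
`fit-fw`, `pvs`, `quantify`, `stats`, `pipeline`) for file-based use with
NIfTI volumes and FSL-style sidecars.

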