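# visionet

Resting-state analysis of vision-related brain networks for case–control
cohorts: voxel-based morphometry (VBM) with permutation/TFCE family-wise
error control, and intra-/inter-network functional connectivity (FC)
statistics over the primary visual (PVN, 2 ROIs), higher visual (HVN,
4 ROIs) and visuospatial (VSN, 13 ROIs) networks — together with a
synthetic-cohort simulator that makes every stage testable against known
ground truth. The study design it implements compares cirrhosis patients
with healthy controls, but the machinery is generic for any two-group
rs-fMRI + gray-matter cohort on a common grid.

## What it computes

**Preprocessing** (per subject): discard the first 4 volumes, exclude
subjects with head motion over 2 mm translation or 2° rotation, band-pass
filter each voxel series to 0.01–0.08 Hz (zero-phase FFT realization;
4th-order Butterworth optional), smooth spatially with a 6 mm FWHM Gaussian
(σ = FWHM / (2√(2 ln 2))).

**Network FC** (per subject): mean time series per atlas ROI; pairwise
Pearson correlations r_ij; Fisher transform z_ij = atanh(r_ij); then

- intra-FC(N) = mean z over unordered ROI pairs within network N,
- inter-FC(M, N) = mean z over ROI pairs straddling M and N,

giving a symmetric 3×3 matrix per subject. Groups are compared entrywise
with pooled two-sample t tests; the Benjamini–Hochberg FDR (q < 0.05) is
controlled separately within the 3 intra and the 3 inter tests. Significant
pairs are correlated against clinical covariates (Pearson r + least-squares
line).

**VBM**: voxel-wise pooled t on gray-matter density maps, threshold-free
cluster enhancement

TFCE(p) = Σ_{h = dh, 2dh, … ≤ t_p} e(h, p)^E · h^H · dh  (E = 0.5, H = 2),

and FWE-corrected p-values from the max-TFCE permutation null,
p = (1 + #{perm max ≥ TFCE_obs}) / (1 + n_perm), with connected-component
cluster reporting at the configured threshold (default p < 0.0002).

The processing stages are also exposed as sklearn-style estimators
(`TemporalBandpass`, `GaussianSmoother`, `NetworkConnectivityMeasure`,
`PermutationVBM`) that compose with sklearn pipelines.

## Worked example

```python
from visionet import SimConfig, RunConfig, generate_cohort, run_pipeline

cfg = SimConfig(n_per_group=6, n_volumes=60, grid_shape=(16, 16, 16),
                gm_effect_d=2.0, seed=42)
generate_cohort(cfg, "demo_cohort")          # BOLD + GM + motion + clinical
res = run_pipeline(RunConfig(manifest="demo_cohort/manifest.json",
                             out_dir="demo_run", n_perm=200,
                             vbm_alpha=0.05, seed=42))
print(res["fc_comparison"].table.round(4).to_string(index=False))
```

prints

```
   pair family  patient_mean  patient_sd  control_mean  control_sd       t  p_raw  p_fdr  significant
    PVN  intra        0.6047      0.3423        0.8933      0.1658 -1.8591 0.0926 0.1390        False
    HVN  intra        0.3434      0.1913        0.4390      0.1449 -0.9761 0.3520 0.3520        False
    VSN  intra        0.2978      0.0668        0.3992      0.0742 -2.4865 0.0322 0.0965        False
PVN-HVN  inter        0.1751      0.1127        0.3972      0.0622 -4.2270 0.0018 0.0053         True
PVN-VSN  inter        0.0198      0.1605        0.0881      0.1494 -0.7626 0.4633 0.4633        False
HVN-VSN  inter        0.0338      0.1338        0.1360      0.1537 -1.2291 0.2472 0.3708        False
```

Each row is one network pair on the Fisher-z scale: group means ± sd, the
pooled t statistic (patients minus controls), the raw and FDR-adjusted p,
and the subsystem-wise rejection. Here the simulator's default targets make
PVN–HVN coupling genuinely lower in patients, and even at n = 6 per group
the comparison flags exactly that pair. The VBM stage recovers the injected
gray-matter deficit as one 74-voxel cluster at the FWE floor
(`res["vbm_clusters"]`: peak p ≈ 0.005 with 200 permutations), and the run
directory contains the QC table, the cluster table, the 3×3 group-mean /
difference matrices (CSV + heat-map) and a markdown report.

A command-line interface wraps the same stages:

```sh
visionet simulate --config cohort.yaml --out cohort/ --seed 7
visionet run --manifest cohort/manifest.json --out run/ --seed 7
```

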