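# Methods

## The analysis model

The package implements a two-group resting-state design over three
vision-related networks: PVN (2 ROIs), HVN (4 ROIs), VSN (13 ROIs), 19 ROIs
in total, taken as a given integer label volume plus a ROI→network table.
Two statistics are computed.

**Network FC.** For each subject, the ROI-mean BOLD series are correlated
pairwise (Pearson), Fisher-transformed (z = atanh r), and averaged into a
3×3 matrix: diagonal = mean z over within-network pairs (intra-FC),
off-diagonal = mean z over straddling pairs (inter-FC). Averaging is done
on the z scale throughout — within subject and across subjects — because z
is variance-stabilizing and approximately normal, which is what the
entrywise pooled t tests assume; an r-scale-first option
(`network_matrix(..., scale="r")`) exists for sensitivity checks and gives
nearly identical group means at these effect sizes. FDR control is applied
separately within the intra family (3 tests) and the inter family
(3 tests): the two subsystems answer different questions (cohesion within a
network vs coupling between networks), and pooling them would let a strong
inter effect buy rejections for intra tests.

**VBM.** Voxel-wise pooled-variance two-sample t on gray-matter density
maps, enhanced with TFCE (discrete sum over thresholds h = dh, 2dh, … with
extent exponent E = 0.5 and height exponent H = 2 — the method's canonical
weights, exposed in `TFCEParams`), and corrected with the max-statistic
permutation null: group labels are permuted, the maximum TFCE over voxels
recorded per permutation, and each voxel's corrected p is
(1 + #{perm max ≥ observed}) / (1 + n_perm). This controls FWE exactly
under exchangeability and explains the p floor 1/(n_perm+1): a reporting
threshold of p < 0.0002 (the default) is only reachable with n_perm ≥ 5000.
Positive and negative contrasts are enhanced separately on t and −t; the
default test is one-sided for the configured contrast (control > patient,
the direction a gray-matter-deficit design predicts), with a two-sided
option on |TFCE|.

## Synthetic cohorts

The generator emulates the study's data structure so each stage can be
validated against ground truth: two groups of 20 subjects, 240 volumes at
TR = 2 s (first 4 discarded downstream), a 24×24×24 grid of 4 mm voxels
holding nineteen 3×3×3-voxel cubic ROIs placed deterministically with a
one-voxel margin.

*BOLD.* ROI signals are multivariate normal with the correlation matrix
implied by a 3×3 z-target: tanh maps targets to r, within-network pairs
share the intra value, cross-network pairs the inter value. Default targets
are the study's printed group-mean matrices, so the simulator's default
patient/control difference is the study's own connectivity pattern. If a
user-supplied target implies a non-PSD matrix it is repaired by eigenvalue
clipping with diagonal renormalization (with a warning), or rejected under
`on_non_psd="raise"`. Every in-ROI voxel carries its ROI signal plus white
noise (sd 0.5 by default) plus drift; background voxels are pure noise.

*Drift.* Two sinusoids with 128 s and 200 s periods — below the 0.01 Hz
band edge, so the filter demonstrably removes them. Phases are drawn per
ROI: drift in a scanner varies spatially, and a globally shared drift would
leak correlated variance into the pass band (the 128 s component sits less
than an octave below the edge, where any finite-window filter leaks ~11% of
its variance) and bias all FC upward. The default amplitude is 0.2× the
signal sd; with per-ROI phases the residual leak then attenuates
correlations by under 2%, keeping the generator inside its own recovery
contract (group-mean z within 0.05 of targets at T = 236, n = 20).

*ROI shortcut.* `generate_roi_signals` produces the same ROI series as
averaging a voxel run with the same seed (noise pre-averaged to sd
noise_sd/√27), which is what makes 100-cohort recovery experiments take
seconds instead of hours; the voxel and shortcut paths are tested for
agreement.

*Gray matter.* A fixed smooth template plus white subject noise (sd 0.1);
patients get the mean inside an effect mask (default: the PVN ROI voxels)
reduced by Cohen's d × noise sd, default d = 1.5 — comfortably detectable
at n = 20 with TFCE, as the study's own deficits were.

*Motion and clinical tables.* Motion traces are clipped random walks
(|value| ≤ 1.5, always passing QC) with an optional injected spike of
2.5–4 units and a ground-truth exclusion label. Clinical covariates are
normal draws with the study's printed moments (age both groups; ammonia,
albumin, bilirubin, prothrombin time for patients only, absent for
controls); normality is assumed from the mean ± SD presentation. Ammonia is
censored at zero rather than rejection-truncated: censoring mimics
below-detection assay reporting and shifts the sample mean by < 1 µmol/L,
so the generated moments still match the published ones.

*Determinism.* Every generator is a pure function of (config, seed);
per-subject streams come from `SeedSequence([master, stream, subject])`, so
resizing a cohort never reshuffles existing subjects.

What the simulator does **not** model: anatomy, hemodynamic response
shapes, spatially correlated noise, registration error, scanner artifacts
beyond drift. Passing tests therefore demonstrate the statistical machinery
is correct and calibrated — not that real MRI idiosyncrasies are handled.

## Numerical choices

- **Band-pass realization**: zero-phase FFT ideal filter (bins strictly
  outside [0.01, 0.08] Hz zeroed). It is a spectral projection — idempotent
  and exactly linear — which makes re-runs stable and contracts testable;
  a 4th-order zero-phase Butterworth is available via
  `realization="butterworth"`.
- **Motion "over 2 mm or 2°"** is strict: exactly 2.0 passes. Rotations are
  compared in degrees directly, no arc-length conversion.
- **Smoothing boundary**: nearest-edge replication; mass-conservation holds
  for interior sources, which is what tests assert.
- **TFCE discretization**: dh defaults to max(stat)/100 per map; the kernel
  is an incremental union-find over descending thresholds (O(V·steps·α)),
  numba-compiled, exact for integer maps with explicit dh and within 2%
  between dh = 0.01 and dh = 0.001 on continuous maps. Thresholding uses
  value ≥ h with a 1e-12 slack against float drift.
- **Zero-variance voxels** get t = 0 (not NaN): synthetic backgrounds are
  constant and must not poison the map.
- **Degenerate r = ±1** is clamped to ±(1 − 1e-7) before atanh with a
  warning — noise-free synthetic runs would otherwise overflow.
- **Connectivity** defaults to 26-neighbour (common VBM practice); 6 is
  available and used in tests where component splitting matters.

## Experiment sizes

The calibration/recovery studies in `visionet.experiments` use the sizes
the package's validation is stated at: 100 repeated 20/20 cohorts for FC
recovery and detection (ROI-shortcut path, T = 236, noise sd 0.5, reduced
inter targets 0.30 → 0.10), and 200 exchangeable null cohorts on a 12³
grid, n = 10/group, 500 permutations, for FWE calibration. These run in
about a minute on one CPU and give Monte-Carlo standard errors of ~0.02 on
the reported rates.

## Known limitations

- No registration, slice-timing correction, nuisance regression or
  cerebellum handling: inputs are assumed co-registered on a common grid,
  as the synthetic data are constructed.
- The per-voxel FWE threshold p < 0.0002 is kept as the reporting default
  for fidelity to the design it implements, but is unattainable below
  n_perm = 5000; the CLI warns by simply returning no clusters.
- Single-ROI networks have undefined intra-FC (reported as missing and
  excluded from testing), and the 3×3 structure is hard-wired to the
  PVN/HVN/VSN triple.
- The permutation test assumes exchangeability under the null; covariate
  adjustment (age, sex) is not implemented — the design relies on matched
  groups.
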