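# Methods

This note documents the models, parameters and design choices behind
`cbfc`, in the order the pipeline runs.

## Synthetic cohort model

The generator produces a two-group (SZ/HC) resting-state cohort on a
common voxel grid, already aligned (no motion corruption or registration
is simulated; motion traces exist for the nuisance design and QC only).

**Atlas geometry.**  The grid is divided into four z-slabs: cerebellum
(bottom ~30%), white matter, CSF (one thin slab each), and cortex (the
rest).  Each network receives one compact cortical territory and one
compact cerebellar territory, grown as nearest-voxel blobs from centers
on a jittered in-plane lattice; territories are pairwise disjoint by
construction and a configuration that does not fit raises an error.  No
anatomical realism is attempted: overlap scoring and cluster inference
need geometry (compact blobs with boundaries), not anatomy.

**Signal model.**  Each network *k* has a latent unit-variance Gaussian
series band-limited to 0.01–0.08 Hz, so planted connectivity survives the
analysis band-pass.  Voxels in both of *k*'s territories receive
`coupling * latent`; the coupling is drawn per subject around the group
value (`coupling_subject_sd`, default 0.05) and recorded as ground truth.
WM and CSF voxels receive their own unit-variance latent series
(amplitude 1).  All voxels add stationary AR(1) noise (innovation SD
`noise_sd` = 1, phi = 0.3, stationary variance `noise_sd^2/(1-phi^2)`),
a linear drift with per-voxel N(0,1) slope scaled by `drift_amp` = 1, and
a cardio-like sinusoid (`cardio_amp` = 0.5 at 0.15 Hz, below the 0.2 Hz
Nyquist at TR 2.5 s) with random per-voxel phase.  The population
variance of a territory voxel is therefore
`c^2 + s^2/(1-phi^2) + drift and cardio terms`, which the tests check.

**Defaults.**  TR 2.5 s, 240 volumes, 30x30x20 grid at 2 mm, 12 subjects
per group, and a ten-network roster mirroring the networks a 17-network
parcellation retains in the cerebellum (ids 3, 4, 6, 7, 8, 9 merged
limbic, 12, 13, 16, 17).  All couplings are 0.6 in controls; the five
association networks (7, 8, 12, 13, 16) are planted hypoconnected in
patients (0.3) and somatomotor A (3) hyperconnected (0.8).  Motion is a
six-parameter random walk with step SDs 0.15 mm / 0.15 deg, which puts
the Jenkinson mean absolute displacement near 0.35 mm, typical of a
clinical resting-state sample.

**Phenotype.**  Ages ~N(38, 10) / N(39, 9) clipped to 18–65, ~40% female,
~39% scanned post-upgrade, chlorpromazine-equivalent doses ~N(580, 618)
truncated at zero for patients (0 for controls).  Five symptom scales
(SAPS 35.8±19.1, SANS 23.5±15.9, YMRS 14.7±8.0, MADRS 14.4±9.3,
PSYRATS-AH 12.7±14.3) are generated for patients only, with a missingness
rate of 0.25 per cell.  Optionally a scale is linked to a network's
coupling deviation (`score = mean + slope * dev + noise`); the default
slope is 0 (pure null).  The documented positive-control preset
(`positive_control_symptom_models`) uses slope 250 on SAPS vs the
ventral-attention network, giving a true correlation ~0.8 — analytic
power ~0.99 at the 0.05/35 threshold with ~30 complete patient pairs.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: hemodynamic response shape, spatially
structured physiological noise, real anatomy and registration error,
scanner drift nonlinearity, motion-correlated artifacts, and symptom
distributions beyond first and second moments.

## Seed construction

The 17-network label volume is resampled to the analysis grid by nearest
neighbour (labels must never be averaged; ties in the half-voxel rounding
are broken deterministically upward), split into per-network masks, the
two limbic networks (9, 10) merged, networks with <= 30 voxels of
cerebellar representation excluded, and each retained mask eroded by one
voxel layer.  "One voxel layer with a 3D kernel" is read as the full
3x3x3 structuring element (a voxel survives iff all 26 neighbours are in
the mask) — the maximally conservative reading for avoiding boundary
contamination; the 6-connectivity cross is available via
`connectivity=6`.  Erosion runs after resampling, matching the order in
which the seed protocol lists the operations.

## Preprocessing

Four volumes are discarded (magnet stabilization), each volume is
smoothed with a 6 mm FWHM Gaussian (sigma = FWHM/2.3548 in mm, reflective
boundaries), and each voxel series is band-passed with Gaussian
running-line filters in the FSL "sigma in volumes" convention:
high-pass = series minus the Gaussian-weighted running mean
(sigma = 1/(2 * 0.009 Hz * TR) = 22.2 volumes at TR 2.5), then low-pass
Gaussian smoothing (sigma = 1/(2 * 0.08 Hz * TR) = 2.5 volumes).  Some
protocol texts print these two sigmas attached to the opposite cutoffs;
the formula admits only this pairing, and a note is logged at
construction.  Truncated kernels at the series edges are renormalized, so
constants are reproduced exactly and the high-pass maps them to zero.
The analytic amplitude response is the Gaussian transfer product
`(1 - exp(-2 pi^2 f^2 sigma_hp^2)) * exp(-2 pi^2 f^2 sigma_lp^2)`
(sigmas in seconds); note that this low-pass already attenuates a 0.03 Hz
probe to ~0.50 — an inherent property of the sigma = 1/(2 f TR)
convention, verified against probe sinusoids in the tests.

Motion QC is the Jenkinson RMS displacement of the relative rigid
transform between consecutive volumes, averaged over pairs:
`sqrt((R^2/5) trace((Q-I)'(Q-I)) + |t|^2)` with R = 80 mm, i.e. the RMS
point displacement over a solid ball (checked against Monte-Carlo ball
sampling).  Rotations compose as Rx·Ry·Rz about the grid origin.

The first-level design has 10 columns — seed, WM mean, CSF mean, six
motion parameters, intercept — with all non-intercept columns
mean-centered.  Nuisance terms enter the same GLM as the seed (not a
pre-regression), so the seed effect is estimated with nuisance variance
partialled out and no regressor reintroduction can occur.  A
rank-deficient design raises an error naming the collinear columns.

## First-level GLM

OLS per cerebellar voxel with classical (homoskedastic) standard errors;
no prewhitening.  The band-pass colours the noise, so first-level dof are
not trusted for inference — validity rests on the group-level
permutation.  The seed t is mapped to z by `z = Phi^-1(F_t(t; dof))`,
computed through the survival function for tail precision and clamped at
|z| = 38 (the double-precision tail limit) with a warning.  Voxels with
zero residual variance (including degenerate perfect fits) are flagged
and given t = 0.  The z maps are passed to the group stage; beta maps are
retained for inspection.

## Group inference

Subject z maps are modelled voxelwise by OLS on
[group, age, sex, cpz, scanner, intercept] (covariates mean-centered;
controls take dose 0; the medication-uncontrolled variant drops the cpz
column).  Directional contrasts are thresholded one-sided at voxel
p < 0.01 (the two directions are run as separate one-sided tests,
matching how both contrast directions are reported); suprathreshold
voxels form 26-connected clusters (configurable; equal-sized clusters are
ordered by peak statistic).

Cluster-extent correction replaces parametric mixed-effects machinery
with Freedman–Lane permutation: the covariate-only model is fitted, its
residuals are row-permuted and added back to the reduced fit, the
full-model contrast map is recomputed, and the maximum cluster size per
permutation forms the null.  Corrected
`p = (1 + #{perm max >= observed size}) / (n_perm + 1)`; with no
covariates the scheme reduces exactly to group-label permutation (tested
by exhaustive enumeration on 3 vs 3).  `n_perm` defaults to 1000 and
values below 20 are refused as too coarse; an `exhaustive` mode
enumerates all distinct group assignments for small cohorts.  Within-group
maps are one-sample t maps across subjects, converted to z, with a
one-sided p map.

## Map overlap and winner-take-all

Overlap metrics are computed per network against the single-network
canonical mask: positives = canonical voxels, negatives = remaining
cerebellar voxels, TP/FP from the binarized group map (one-sided p < 0.05
uncorrected by default — the display-threshold convention — with the
alpha configurable), TN = N − FP.  Accuracy, sensitivity and specificity
follow; Dice is available as an auxiliary measure.  The winner-take-all
labeller assigns each cerebellar voxel to the network with the maximal
statistic (ties to the lowest id, counted and logged); it is used to
build synthetic canonical references, never re-fed into inference.

## Symptom correlation

For each contrast with significant clusters, the mean preprocessed series
over the union of its clusters is correlated with the seed series (one
Pearson r per subject), and those values are correlated with the five
scales over patients.  Missing scores are handled pairwise-complete
(matching per-scale sample sizes implied by typical missingness
footnotes); cells with fewer than 3 complete pairs are marked
not-computable.  p values are two-sided.  The family threshold is the
exact alpha/m (0.05/35 ≈ 0.00143) by default, with a compatibility flag
for the rounded p < 0.001 convention.

## Validation experiments and problem sizes

Three experiments validate the pipeline end to end, all driven by the
generator's ground truth:

- **Type-I calibration**: 200 null cohorts (8 vs 8 subjects, 20x20x12
  grid, 120 volumes, two equal-coupling networks, 200 permutations); the
  fraction of cohorts with any significant cluster should sit near the
  nominal 0.05.  Cohort draws whose design is rank deficient (e.g. a
  single-sex sample, possible at n = 16) are redrawn deterministically.
- **Recovery**: 20 replicate cohorts (20 vs 20 subjects, one network
  planted 0.6 → 0.3, two unplanted); success requires a significant
  HC > SZ cluster with Dice >= 0.5 against the planted territory, and
  unplanted networks should rarely flag.
- **Map fidelity**: within-group maps of the default cohort scored
  against the planted atlas; accuracy lands near 0.90 per network.
  Spatial smoothing spreads each territory's genuine signal into a
  false-positive ring around it, which caps specificity near 0.9 — the
  same mechanism that limits specificity in real cohorts — so accuracy
  for the worst-placed network can approach the high 0.8s depending on
  the realization.

`scripts/acceptance.py` reruns these (100 null cohorts, 20 recovery
replicates, 200 permutations each — sizes chosen so the whole script
finishes in a few minutes on a single CPU), along with the analytic
constants (filter sigmas, seed roster, Bonferroni family), the
within-group map accuracies, motion QC, and the band-pass frequency
response.

## Known limitations

- Homoskedastic OLS at both levels; no variance-component modelling.
  Permutation supplies group-level validity, but between-subject variance
  heterogeneity is not modelled.
- The synthetic atlas is slab-based; partial-volume effects, folding and
  true homotopy are absent, so overlap numbers are not comparable in
  detail to any real parcellation.
- Real-data ingestion (slice-time/motion correction, registration) is out
  of scope; NIfTI inputs are assumed aligned on a common grid.
- The band-pass is a dense linear operator (O(T^2) per voxel), fine for
  resting-state lengths but not for long recordings.
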