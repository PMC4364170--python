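# cbfc — cerebro-cerebellar functional connectivity

`cbfc` is a tested Python implementation of a seed-based resting-state
functional-connectivity analysis of the cerebellum, of the kind used to
compare cerebro-cerebellar network coupling between schizophrenia patients
and healthy controls.  Cortical seeds are built from a 17-network
functional parcellation; every cerebellar voxel is regressed on each
seed's mean BOLD time course with white-matter, CSF and motion nuisance
covariates; group contrasts are tested with cluster-extent permutation
inference; thresholded group maps are scored against a canonical
cerebellar parcellation; and cluster-wise connectivity is correlated with
clinical symptom scales.

Because the clinical scans such analyses run on are never distributable,
the package ships a first-class **synthetic cohort generator**: two-group
cohorts with planted network structure (homotopic cortical and cerebellar
territories sharing band-limited latent signals), AR(1) noise, drift,
cardio-like nuisance, WM/CSF compartments, motion traces, and a phenotype
table with symptom scales.  Every downstream stage can therefore be
exercised — and validated against known ground truth — with no data
download.

## The analysis in brief

For subject *s* and network *k*, each cerebellar voxel *v* is fit by OLS:

```
y_v(t) = beta_seed * x_k(t) + beta_wm * wm(t) + beta_csf * csf(t)
         + motion(t) * b + intercept + e(t)
```

where `x_k` is the mean series of the eroded cortical seed.  The seed t
statistic is mapped to z by the quantile transform `z = Phi^-1(F_t(t))`.
Preprocessing follows the standard volume protocol: discard 4 volumes,
6 mm FWHM Gaussian smoothing, and a Gaussian running-line band-pass
(0.009–0.08 Hz; sigma = 1/(2·f·TR), i.e. 22.2 and 2.5 volumes at
TR = 2.5 s).  Group contrasts (SZ > HC, HC > SZ) with age, sex,
chlorpromazine-equivalent and scanner-upgrade covariates are thresholded
one-sided at voxel p < 0.01 and cluster-corrected at p < 0.05 by
Freedman–Lane permutation of the max-cluster-size statistic.  Group-map
overlap with a canonical cerebellar map is quantified as

```
accuracy    = (TP + TN) / (P + N)
sensitivity = TP / P
specificity = TN / N
```

with P the canonical-map voxels and N the remaining cerebellar voxels.
Symptom associations use Pearson correlation over the 5-scale x
7-contrast matrix with Bonferroni control (0.05 / 35 per test).

## Worked example

Simulate a small two-group cohort in which network 1's cerebro-cerebellar
coupling is planted lower in the patient group (0.3 vs 0.6), then test the
HC > SZ contrast:

```python
from cbfc import pipeline
from cbfc.synthetic import CohortSpec, NetworkSpec
from cbfc.overlap import dice

spec = CohortSpec(
    n_per_group=8, grid_shape=(20, 20, 12), n_volumes=120,
    networks=[NetworkSpec(1, cortical_size=80, cerebellar_size=60,
                          coupling_hc=0.6, coupling_sz=0.3),
              NetworkSpec(2, cortical_size=80, cerebellar_size=60,
                          coupling_hc=0.6, coupling_sz=0.6)],
    rng_seed=1,
)
cohort = pipeline.run_synthetic_cohort(spec)
cfg = pipeline.PipelineConfig(n_perm=500)
table, labels, _ = pipeline.group_contrast_clusters(
    cohort, "1", "hc_gt_sz", cfg, rng_seed=5)
print(table)
```

```
 cluster_id  n_voxels  peak_stat  peak_i  peak_j  peak_k   p_corr  significant
          1        85   3.699119       4      12       2 0.005988         True
          2         3   2.501850       9      14       0 0.680639        False
```

The 85-voxel cluster (corrected p = 0.006) overlaps the planted cerebellar
territory with Dice 0.607; the equal-coupling network 2 yields nothing.
The within-group HC maps, thresholded at p < 0.05 uncorrected and scored
against the planted territories, give

```
seed_id  accuracy  sensitivity  specificity
      1     0.841          1.0        0.834
      2     0.873          1.0        0.868
```

i.e. every planted voxel is recovered and the false-positive ring from
spatial smoothing caps specificity — the same behaviour reported for
real cohorts.

A shell interface wraps the same stages:

```
cbfc simulate --config cohort.yaml --out cohort/
cbfc seeds --parcellation cortical_labels.nii --cerebellar cerebellar_labels.nii --out seeds/
cbfc preprocess --bold sub-SZ01_bold.nii --motion sub-SZ01_motion.par --out pp.nii
cbfc group --cohort cohort/ --contrast hc_gt_sz --nperm 1000 --seed 7 --out results/
cbfc symptoms --fc fc.tsv --phenotype cohort/participants.tsv --out corr.tsv
```

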