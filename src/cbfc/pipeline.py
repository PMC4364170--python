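"""End-to-end orchestration: cohort -> seeds -> first-level maps -> inference.

Thin glue over the stage modules, used by the command-line interface and
by the validation experiments (null calibration, planted-effect recovery,
map-fidelity scoring).  All stages run in memory; cohort data can come
from the synthetic generator directly or from files written by
``simulate_cohort``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import synthetic
from .first_level import FCMap, fit_voxelwise_glm
from .group import (
    GroupDesign,
    build_group_design,
    permutation_cluster_pvalues,
    within_group_map,
)
from .overlap import binarize_map, confusion_counts, dice, overlap_metrics
from .preprocess import (
    BoldSeries,
    FilterSpec,
    MotionParams,
    bandpass_temporal,
    build_first_level_design,
    drop_initial_volumes,
    extract_mean_timecourse,
    smooth_spatial,
)
from .seeds import SeedSet, build_seed_set
from .synthetic import AtlasBundle, CohortSpec, SubjectRecord


@dataclass
class PipelineConfig:
    """Analysis-stage parameters (the study protocol's defaults)."""

    n_discard: int = 4
    fwhm_mm: float = 6.0
    voxel_mm: float = 2.0
    f_low_hz: float = 0.009
    f_high_hz: float = 0.08
    voxel_p: float = 0.01
    cluster_p: float = 0.05
    n_perm: int = 1000
    map_alpha: float = 0.05      # display/overlap threshold, uncorrected
    include_cpz: bool = True
    smooth: bool = True


def preprocess_subject(
    bold: BoldSeries, motion: MotionParams, cfg: PipelineConfig
) -> tuple[BoldSeries, MotionParams]:
    """Volume discard, spatial smoothing and temporal band-pass for one subject."""
    bold, motion = drop_initial_volumes(bold, cfg.n_discard, motion)
    if cfg.smooth:
        bold = smooth_spatial(bold, cfg.fwhm_mm, cfg.voxel_mm)
    fs = FilterSpec(cfg.f_low_hz, cfg.f_high_hz, bold.tr_seconds)
    bold = bandpass_temporal(bold, fs)
    return bold, motion


def subject_network_maps(
    bold: BoldSeries,
    motion: MotionParams,
    atlas: AtlasBundle,
    seed_set: SeedSet,
    cfg: PipelineConfig,
    subject_id: str = "",
) -> dict[str, FCMap]:
    """Preprocess one subject and fit the voxelwise GLM for every seed."""
    bold, motion = preprocess_subject(bold, motion, cfg)
    wm_tc = extract_mean_timecourse(bold, atlas.wm_mask)
    csf_tc = extract_mean_timecourse(bold, atlas.csf_mask)
    maps: dict[str, FCMap] = {}
    for seed in seed_set:
        seed_tc = extract_mean_timecourse(bold, seed.mask)
        design = build_first_level_design(seed_tc, wm_tc, csf_tc, motion)
        maps[seed.seed_id] = fit_voxelwise_glm(
            bold, atlas.cerebellum_mask, design,
            network_id=seed.seed_id, subject_id=subject_id,
        )
    return maps


def seed_set_from_atlas(atlas: AtlasBundle, threshold: int = 30) -> SeedSet:
    """Build the analysis seeds from an atlas bundle (split/merge/select/erode)."""
    return build_seed_set(atlas.cortical_labels, atlas.cerebellar_labels,
                          threshold=threshold)


@dataclass
class CohortMaps:
    """First-level maps for a whole cohort, ready for the group stage."""

    atlas: AtlasBundle
    seed_set: SeedSet
    records: list[SubjectRecord]
    phenotype: pd.DataFrame
    maps: dict[str, list[FCMap]]    # seed_id -> one map per subject, cohort order
    preprocessed: list[BoldSeries] = field(default_factory=list)
    seed_tcs: dict[str, list[np.ndarray]] = field(default_factory=dict)


def run_synthetic_cohort(
    spec: CohortSpec,
    cfg: PipelineConfig | None = None,
    keep_bold: bool = False,
) -> CohortMaps:
    """Simulate a cohort and compute all first-level maps in memory.

    ``keep_bold`` retains each subject's preprocessed series and seed time
    courses for the symptom-correlation stage (memory permitting).
    """
    cfg = cfg or PipelineConfig()
    atlas = synthetic.make_atlas(spec)
    records = synthetic.make_cohort_records(spec)
    seed_set = seed_set_from_atlas(atlas)
    maps: dict[str, list[FCMap]] = {s.seed_id: [] for s in seed_set}
    kept: list[BoldSeries] = []
    seed_tcs: dict[str, list[np.ndarray]] = {s.seed_id: [] for s in seed_set}
    for i, rec in enumerate(records):
        bold, motion = synthetic.simulate_subject(
            atlas, rec, spec, synthetic.subject_rng(spec, i)
        )
        bold_pp, motion_pp = preprocess_subject(bold, motion, cfg)
        wm_tc = extract_mean_timecourse(bold_pp, atlas.wm_mask)
        csf_tc = extract_mean_timecourse(bold_pp, atlas.csf_mask)
        for seed in seed_set:
            seed_tc = extract_mean_timecourse(bold_pp, seed.mask)
            design = build_first_level_design(seed_tc, wm_tc, csf_tc, motion_pp)
            maps[seed.seed_id].append(fit_voxelwise_glm(
                bold_pp, atlas.cerebellum_mask, design,
                network_id=seed.seed_id, subject_id=rec.subject_id,
            ))
            if keep_bold:
                seed_tcs[seed.seed_id].append(seed_tc)
        if keep_bold:
            kept.append(bold_pp)
    return CohortMaps(
        atlas=atlas, seed_set=seed_set, records=records,
        phenotype=synthetic.records_to_frame(records),
        maps=maps, preprocessed=kept, seed_tcs=seed_tcs,
    )


def group_contrast_clusters(
    cohort: CohortMaps,
    seed_id: str,
    contrast: str,
    cfg: PipelineConfig,
    rng_seed: int,
):
    """Permutation cluster inference for one seed and directional contrast."""
    gd = build_group_design(cohort.phenotype, include_cpz=cfg.include_cpz)
    return permutation_cluster_pvalues(
        cohort.maps[seed_id], gd, contrast,
        voxel_p=cfg.voxel_p, n_perm=cfg.n_perm, rng_seed=rng_seed,
        cluster_p=cfg.cluster_p,
    )


# ---------------------------------------------------------------------------
# Validation experiments: type-I calibration and planted-effect recovery
# ---------------------------------------------------------------------------

def null_cohort_spec(rng_seed: int) -> CohortSpec:
    """Reduced-scale cohort with no group difference in any network."""
    from .synthetic import NetworkSpec

    return CohortSpec(
        n_per_group=8, grid_shape=(20, 20, 12), n_volumes=120,
        networks=[
            NetworkSpec(1, cortical_size=80, cerebellar_size=60,
                        coupling_hc=0.5, coupling_sz=0.5),
            NetworkSpec(2, cortical_size=80, cerebellar_size=60,
                        coupling_hc=0.5, coupling_sz=0.5),
        ],
        rng_seed=rng_seed,
    )


def recovery_cohort_spec(rng_seed: int) -> CohortSpec:
    """Reduced-scale cohort with one network planted hypoconnected (0.6 -> 0.3)."""
    from .synthetic import NetworkSpec

    return CohortSpec(
        n_per_group=20, grid_shape=(20, 20, 12), n_volumes=120,
        networks=[
            NetworkSpec(1, cortical_size=80, cerebellar_size=60,
                        coupling_hc=0.6, coupling_sz=0.3),
            NetworkSpec(2, cortical_size=80, cerebellar_size=60,
                        coupling_hc=0.6, coupling_sz=0.6),
            NetworkSpec(3, cortical_size=80, cerebellar_size=60,
                        coupling_hc=0.6, coupling_sz=0.6),
        ],
        rng_seed=rng_seed,
    )


def _cohort_with_valid_design(spec_factory, rng_seed: int, include_cpz: bool,
                              cfg: PipelineConfig):
    """Simulate a cohort, redrawing if a covariate came out constant.

    Small cohorts can by chance draw a single-sex or single-scanner sample,
    which makes the group design rank deficient; such draws carry no
    information about the analysis and are replaced deterministically.
    """
    seed = rng_seed
    for _ in range(20):
        cohort = run_synthetic_cohort(spec_factory(seed), cfg)
        try:
            build_group_design(cohort.phenotype, include_cpz=include_cpz)
            return cohort
        except ValueError:
            seed += 100_003
    raise RuntimeError("could not draw a cohort with a full-rank design")


def run_null_calibration(
    n_cohorts: int = 200,
    base_seed: int = 0,
    n_perm: int = 200,
    cfg: PipelineConfig | None = None,
) -> dict:
    """Family-wise error of the cluster test on null cohorts.

    Simulates ``n_cohorts`` no-effect cohorts, runs the HC > SZ cluster
    permutation test on the first network, and reports the fraction of
    cohorts with at least one significant cluster (nominal 0.05).
    """
    cfg = cfg or PipelineConfig(n_perm=n_perm)
    cfg.n_perm = n_perm
    hits = 0
    for i in range(n_cohorts):
        cohort = _cohort_with_valid_design(
            null_cohort_spec, base_seed + i, cfg.include_cpz, cfg
        )
        table, _, _ = group_contrast_clusters(
            cohort, "1", "hc_gt_sz", cfg, rng_seed=base_seed + 7919 * (i + 1)
        )
        hits += int(len(table) > 0 and table["significant"].any())
    return {"n_cohorts": n_cohorts, "fwer": hits / n_cohorts}


def run_recovery(
    n_replicates: int = 20,
    base_seed: int = 0,
    n_perm: int = 200,
    cfg: PipelineConfig | None = None,
) -> dict:
    """Recovery of a planted hypoconnectivity effect.

    For each replicate cohort the HC > SZ contrast is run for every
    network; success for the planted network means at least one significant
    cluster with Dice >= 0.5 against the planted cerebellar territory.
    Reports the planted success rate, the per-replicate best Dice values,
    and the false-flag rate pooled over unplanted networks.
    """
    cfg = cfg or PipelineConfig(n_perm=n_perm)
    cfg.n_perm = n_perm
    planted_hits, dices = 0, []
    unplanted_flags, unplanted_total = 0, 0
    for i in range(n_replicates):
        cohort = _cohort_with_valid_design(
            recovery_cohort_spec, base_seed + i, cfg.include_cpz, cfg
        )
        for seed in cohort.seed_set:
            table, labels, _ = group_contrast_clusters(
                cohort, seed.seed_id, "hc_gt_sz", cfg,
                rng_seed=base_seed + 104_729 * (i + 1) + int(seed.seed_id),
            )
            sig = table[table["significant"]] if len(table) else table
            if seed.seed_id == "1":
                planted = cohort.atlas.network_cerebellar_mask(1)
                best = max(
                    (dice(labels == cid, planted) for cid in sig["cluster_id"]),
                    default=0.0,
                )
                dices.append(best)
                planted_hits += int(best >= 0.5)
            else:
                unplanted_total += 1
                unplanted_flags += int(len(sig) > 0)
    return {
        "n_replicates": n_replicates,
        "planted_success_rate": planted_hits / n_replicates,
        "dice": dices,
        "unplanted_flag_rate": unplanted_flags / unplanted_total,
    }


def within_group_overlap(
    cohort: CohortMaps, group: str, cfg: PipelineConfig
) -> pd.DataFrame:
    """Per-network overlap of the within-group map with the planted atlas.

    The within-group one-sample map is thresholded one-sided at the
    uncorrected display alpha and scored against the network's canonical
    (planted) cerebellar territory.
    """
    groups = [r.group for r in cohort.records]
    rows = []
    for seed in cohort.seed_set:
        gsm = within_group_map(cohort.maps[seed.seed_id], groups=groups, group=group)
        gmask = binarize_map(gsm, cohort.atlas.cerebellum_mask, alpha=cfg.map_alpha)
        canonical = np.zeros_like(gmask)
        for nid in seed.member_ids:
            canonical |= cohort.atlas.network_cerebellar_mask(nid)
        cc = confusion_counts(gmask, canonical, cohort.atlas.cerebellum_mask)
        metrics = overlap_metrics(cc)
        rows.append({
            "seed_id": seed.seed_id, "group": group,
            "p_voxels": cc.p, "n_voxels": cc.n, "tp": cc.tp, "fp": cc.fp, "tn": cc.tn,
            **metrics,
            "dice": dice(gmask, canonical),
        })
    return pd.DataFrame(rows)
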