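"""Group-level contrasts with cluster-extent permutation inference.

Subject-level z maps are modelled voxelwise by OLS on a group design
(group indicator plus age, sex, chlorpromazine-equivalent dose and
scanner-upgrade covariates).  Directional contrasts (SZ > HC and HC > SZ)
are thresholded one-sided at voxel p < 0.01 and the surviving voxels are
grouped into 26-connected clusters; cluster extent is tested against a
max-cluster-size null distribution built by Freedman-Lane permutation
(permute the residuals of the covariate-only model), with corrected
p = (1 + #{perm max >= observed size}) / (n_perm + 1) and a p < 0.05
cluster threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .first_level import FCMap, t_to_z

DEFAULT_VOXEL_P = 0.01
DEFAULT_CLUSTER_P = 0.05
DEFAULT_N_PERM = 1000


@dataclass
class GroupDesign:
    """Between-subject design: rows are subjects, one row per first-level map."""

    matrix: np.ndarray
    names: list[str]
    contrasts: dict[str, np.ndarray]
    subject_ids: list[str]

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]


@dataclass
class GroupStatMap:
    """Voxelwise group statistic over the cerebellum mask."""

    t: np.ndarray
    z: np.ndarray
    mask: np.ndarray
    dof: int
    degenerate: np.ndarray       # voxels with no residual variance (stat forced to 0)
    p_one_sided: np.ndarray | None = None


def build_group_design(records: pd.DataFrame, include_cpz: bool = True) -> GroupDesign:
    """Build the group design from a phenotype table.

    ``records`` needs columns ``subject_id, group (SZ/HC), age, sex (F/M),
    cpz, scanner_flag (pre/post)``.  Covariates are mean-centered; healthy
    controls take a chlorpromazine-equivalent dose of 0.  ``include_cpz``
    switches between the primary (medication-controlled) and exploratory
    designs.
    """
    rec = records.reset_index(drop=True)
    cols = {"group": (rec["group"] == "SZ").astype(float)}
    cols["age"] = pd.to_numeric(rec["age"], errors="coerce")
    cols["sex"] = (rec["sex"] == "F").astype(float)
    if include_cpz:
        cpz = pd.to_numeric(rec["cpz"], errors="coerce")
        cpz = cpz.where(rec["group"] == "SZ", 0.0)  # controls are unmedicated
        cols["cpz"] = cpz
    cols["scanner"] = (rec["scanner_flag"] == "post").astype(float)

    missing_by_subject: dict[str, list[str]] = {}
    for name, col in cols.items():
        bad = rec.loc[np.asarray(~np.isfinite(col.to_numpy(dtype=float))), "subject_id"]
        for s in bad:
            missing_by_subject.setdefault(str(s), []).append(name)
    if missing_by_subject:
        raise ValueError(f"missing covariates: {missing_by_subject}")

    x = np.column_stack([np.asarray(c, dtype=float) for c in cols.values()])
    x = x - x.mean(axis=0, keepdims=True)
    x = np.column_stack([x, np.ones(len(rec))])
    names = list(cols) + ["intercept"]
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("group design is rank deficient (constant or collinear column)")
    c_sz = np.zeros(x.shape[1])
    c_sz[names.index("group")] = 1.0
    contrasts = {"sz_gt_hc": c_sz, "hc_gt_sz": -c_sz}
    return GroupDesign(x, names, contrasts, [str(s) for s in rec["subject_id"]])


def _stack_maps(maps, mask=None):
    """(n_subjects, n_voxels) matrix of z values over the common mask."""
    if (isinstance(maps, tuple) and len(maps) == 2
            and isinstance(maps[0], np.ndarray) and maps[0].ndim == 2):
        maps, mask = maps
    if isinstance(maps, np.ndarray) and maps.ndim == 2:
        if mask is None:
            raise ValueError("mask required with a pre-stacked value matrix")
        return np.asarray(maps, dtype=float), np.asarray(mask).astype(bool)
    arrs = []
    for m in maps:
        if isinstance(m, FCMap):
            if mask is None:
                mask = m.mask
            arrs.append(m.z[mask])
        else:
            a = np.asarray(m, dtype=float)
            if mask is None:
                raise ValueError("mask required with raw arrays")
            arrs.append(a[mask])
    return np.vstack(arrs), np.asarray(mask).astype(bool)


def _contrast_t(y: np.ndarray, x: np.ndarray, c: np.ndarray):
    """Voxelwise OLS contrast t statistics for y (n_subjects, n_voxels)."""
    n, p = x.shape
    dof = n - p
    pinv = np.linalg.pinv(x)
    beta = pinv @ y
    resid = y - x @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    cvar = float(c @ (pinv @ pinv.T) @ c)
    se2 = rss / dof * cvar
    eff = c @ beta
    degen = se2 <= np.finfo(float).eps * np.maximum(1.0, eff**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degen, 0.0, eff / np.sqrt(se2))
    return t, dof, degen


def fit_group_contrast(maps, gd: GroupDesign, contrast) -> GroupStatMap:
    """Voxelwise contrast of subject z maps on the group design, as a z map."""
    c = gd.contrasts[contrast] if isinstance(contrast, str) else np.asarray(contrast, float)
    y, mask = _stack_maps(maps)
    if y.shape[0] != gd.n_subjects:
        raise ValueError("map count must equal design rows")
    t, dof, degen = _contrast_t(y, gd.matrix, c)
    z = t_to_z(t, dof)

    def embed(v):
        out = np.zeros(mask.shape)
        out[mask] = v
        return out

    return GroupStatMap(embed(t), embed(np.atleast_1d(z)), mask, dof,
                        embed(degen.astype(float)).astype(bool))


def within_group_map(maps, groups=None, group=None) -> GroupStatMap:
    """One-sample t map across subjects (optionally restricted to one group).

    Tests the mean z value against zero at each voxel; returns t, z and the
    one-sided (positive) p map.  Zero-variance voxels are flagged and set
    to 0.
    """
    if groups is not None:
        groups = np.asarray(groups)
        maps = [m for m, g in zip(maps, groups) if g == group]
    y, mask = _stack_maps(maps)
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects for a within-group map")
    mean = y.mean(axis=0)
    sd = y.std(axis=0, ddof=1)
    degen = sd <= np.finfo(float).eps * np.maximum(1.0, np.abs(mean))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degen, 0.0, mean / (sd / np.sqrt(n)))
    dof = n - 1
    z = t_to_z(t, dof)
    p = stats.t.sf(t, dof)

    def embed(v, fill=0.0):
        out = np.full(mask.shape, fill)
        out[mask] = v
        return out

    return GroupStatMap(embed(t), embed(np.atleast_1d(z)), mask, dof,
                        embed(degen.astype(float)).astype(bool),
                        p_one_sided=embed(p, fill=1.0))


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


def _cluster_sizes(supra_3d: np.ndarray, structure: np.ndarray):
    labels, n = ndimage.label(supra_3d, structure=structure)
    if n == 0:
        return labels, np.array([], dtype=int)
    return labels, np.bincount(labels.ravel())[1:]


def extract_clusters(
    stat_map,
    mask=None,
    voxel_p: float = DEFAULT_VOXEL_P,
    connectivity: int = 26,
):
    """Threshold a z map one-sided at ``voxel_p`` and label connected clusters.

    Returns (table, label_volume); the table is sorted by cluster size
    (ties broken by peak statistic) and ids are reassigned in that order.
    """
    if isinstance(stat_map, GroupStatMap):
        z, mask = stat_map.z, stat_map.mask
    else:
        z = np.asarray(stat_map, dtype=float)
        if mask is None:
            mask = np.ones(z.shape, dtype=bool)
    if not (0 < voxel_p < 1):
        raise ValueError("voxel_p must be in (0, 1)")
    zcrit = stats.norm.isf(voxel_p)
    supra = (z >= zcrit) & mask
    structure = _connectivity_structure(connectivity)
    labels, sizes = _cluster_sizes(supra, structure)
    rows = []
    for lab in range(1, sizes.size + 1):
        where = labels == lab
        peak_flat = np.argmax(np.where(where, z, -np.inf))
        pk = np.unravel_index(peak_flat, z.shape)
        rows.append({
            "cluster_id": lab,
            "n_voxels": int(sizes[lab - 1]),
            "peak_stat": float(z[pk]),
            "peak_i": int(pk[0]), "peak_j": int(pk[1]), "peak_k": int(pk[2]),
        })
    table = pd.DataFrame(rows, columns=["cluster_id", "n_voxels", "peak_stat",
                                        "peak_i", "peak_j", "peak_k"])
    if len(table):
        table = table.sort_values(["n_voxels", "peak_stat"],
                                  ascending=False).reset_index(drop=True)
        relabel = np.zeros(sizes.size + 1, dtype=np.int32)
        for new_id, old_id in enumerate(table["cluster_id"], start=1):
            relabel[old_id] = new_id
        labels = relabel[labels]
        table["cluster_id"] = np.arange(1, len(table) + 1)
    return table, labels


def _assignment_permutations(groups01: np.ndarray):
    """All distinct relabelings of a binary group vector, as row permutations."""
    n = groups01.size
    ones = int(groups01.sum())
    idx_one = np.flatnonzero(groups01)
    idx_zero = np.flatnonzero(groups01 == 0)
    perms = []
    for new_ones in combinations(range(n), ones):
        new_ones = np.array(new_ones, dtype=int)
        new_zeros = np.setdiff1d(np.arange(n), new_ones, assume_unique=False)
        # permuted data y[pi] places the target rows at the design's group-1
        # positions, so the effective assignment is exactly `new_ones`
        pi = np.empty(n, dtype=int)
        pi[idx_one] = new_ones
        pi[idx_zero] = new_zeros
        perms.append(pi)
    return perms


def permutation_cluster_pvalues(
    maps,
    gd: GroupDesign,
    contrast,
    voxel_p: float = DEFAULT_VOXEL_P,
    n_perm: int = DEFAULT_N_PERM,
    rng_seed: int | None = None,
    connectivity: int = 26,
    cluster_p: float = DEFAULT_CLUSTER_P,
    exhaustive: bool = False,
):
    """Cluster-extent corrected inference by Freedman-Lane permutation.

    The covariate-only (reduced) model is fitted voxelwise; its residuals
    are row-permuted, added back to the reduced fit, and the full-model
    contrast map is recomputed to build the null distribution of the
    maximum cluster size.  ``exhaustive=True`` enumerates every distinct
    group assignment (feasible only for small cohorts) and computes the
    exact permutation p including the identity; otherwise ``n_perm`` random
    permutations give p = (1 + #{perm max >= observed}) / (n_perm + 1).

    Returns (table, label_volume, null_max_sizes).
    """
    c = gd.contrasts[contrast] if isinstance(contrast, str) else np.asarray(contrast, float)
    y, mask = _stack_maps(maps)
    if y.shape[0] != gd.n_subjects:
        raise ValueError("map count must equal design rows")
    x = gd.matrix
    n, p = x.shape
    structure = _connectivity_structure(connectivity)

    # observed statistics; threshold on t (equivalent to z >= Phi^-1(1 - voxel_p))
    t_obs, dof, _ = _contrast_t(y, x, c)
    tcrit = stats.t.isf(voxel_p, dof)
    supra = np.zeros(mask.shape, dtype=bool)
    supra[mask] = t_obs >= tcrit
    labels, sizes = _cluster_sizes(supra, structure)

    # reduced model: columns not involved in the contrast
    keep = np.abs(c) == 0
    x0 = x[:, keep]
    h0 = x0 @ np.linalg.pinv(x0)
    fitted = h0 @ y
    resid = y - fitted

    pinv = np.linalg.pinv(x)
    cvar = float(c @ (pinv @ pinv.T) @ c)
    a_row = (c @ pinv)                      # effect = a_row @ y
    m_resid = np.eye(n) - x @ pinv          # residual maker of the full model
    eps = np.finfo(float).eps

    def max_cluster_size(y_perm) -> int:
        eff = a_row @ y_perm
        rss = np.einsum("ij,ij->j", m_resid @ y_perm, m_resid @ y_perm)
        se2 = rss / dof * cvar
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se2 <= eps * np.maximum(1.0, eff**2), 0.0, eff / np.sqrt(se2))
        s3 = np.zeros(mask.shape, dtype=bool)
        s3[mask] = t >= tcrit
        _, szs = _cluster_sizes(s3, structure)
        return int(szs.max()) if szs.size else 0

    if exhaustive:
        groups01 = (x[:, gd.names.index("group")] > x[:, gd.names.index("group")].mean()
                    ).astype(int) if "group" in gd.names else None
        if groups01 is None:
            raise ValueError("exhaustive mode needs a group column")
        perms = _assignment_permutations(groups01)
        null_max = np.array([max_cluster_size(fitted + resid[pi]) for pi in perms])
        denom = len(perms)
        p_corr = np.array([(null_max >= s).sum() / denom for s in sizes])
    else:
        if n_perm < 20:
            raise ValueError("n_perm < 20 gives too coarse a p resolution; refuse")
        rng = np.random.default_rng(rng_seed)
        null_max = np.empty(n_perm, dtype=int)
        for b in range(n_perm):
            pi = rng.permutation(n)
            null_max[b] = max_cluster_size(fitted + resid[pi])
        p_corr = np.array([(1 + (null_max >= s).sum()) / (n_perm + 1) for s in sizes])

    table, labels = extract_clusters(
        _embed_t_as_z(t_obs, mask, dof), mask, voxel_p, connectivity
    )
    # map corrected p onto the sorted table via cluster size ordering
    if len(table):
        order = np.argsort(-sizes, kind="stable")
        # extract_clusters sorts by (size, peak); sizes alone may tie, so match
        # each table row to an unused original cluster of the same size
        remaining = list(np.sort(sizes)[::-1])
        p_by_size: dict[int, list[float]] = {}
        for s, pc in zip(sizes, p_corr):
            p_by_size.setdefault(int(s), []).append(float(pc))
        p_col = [p_by_size[int(s)].pop() for s in table["n_voxels"]]
        table["p_corr"] = p_col
        table["significant"] = table["p_corr"] < cluster_p
        del order, remaining
    else:
        table["p_corr"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return table, labels, null_max


def _embed_t_as_z(t_vec, mask, dof):
    z = np.zeros(mask.shape)
    z[mask] = np.atleast_1d(t_to_z(t_vec, dof))
    return z
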