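"""Group design, contrasts, cluster extraction and permutation inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cbfc.group import (
    GroupDesign,
    build_group_design,
    extract_clusters,
    fit_group_contrast,
    permutation_cluster_pvalues,
    within_group_map,
)


def _pheno(n_sz=3, n_hc=3, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, n in (("SZ", n_sz), ("HC", n_hc)):
        for i in range(n):
            rows.append({
                "subject_id": f"{g}{i}", "group": g,
                "age": float(rng.integers(20, 60)),
                "sex": "F" if rng.random() < 0.5 else "M",
                "cpz": float(rng.integers(100, 900)) if g == "SZ" else np.nan,
                "scanner_flag": "post" if rng.random() < 0.5 else "pre",
            })
    return pd.DataFrame(rows)


def _manual_design(groups01):
    """Group-indicator + intercept design, no covariates."""
    g = np.asarray(groups01, dtype=float)
    x = np.column_stack([g - g.mean(), np.ones(g.size)])
    c = np.array([1.0, 0.0])
    return GroupDesign(x, ["group", "intercept"],
                       {"sz_gt_hc": c, "hc_gt_sz": -c},
                       [str(i) for i in range(g.size)])


class TestGroupDesign:
    def test_primary_design_has_six_columns(self):
        gd = build_group_design(_pheno(), include_cpz=True)
        assert gd.matrix.shape == (6, 6)
        assert np.linalg.matrix_rank(gd.matrix) == 6
        assert gd.names == ["group", "age", "sex", "cpz", "scanner", "intercept"]

    def test_exploratory_design_drops_cpz(self):
        gd = build_group_design(_pheno(), include_cpz=False)
        assert gd.matrix.shape == (6, 5)
        assert "cpz" not in gd.names

    def test_constant_covariate_rejected(self):
        ph = _pheno()
        ph["sex"] = "F"
        with pytest.raises(ValueError, match="rank deficient"):
            build_group_design(ph)

    def test_missing_covariate_names_subject(self):
        ph = _pheno()
        ph.loc[1, "age"] = np.nan
        with pytest.raises(ValueError, match=ph.loc[1, "subject_id"]):
            build_group_design(ph)

    def test_hc_cpz_defaults_to_zero_dose(self):
        gd = build_group_design(_pheno(), include_cpz=True)
        cpz = gd.matrix[:, gd.names.index("cpz")]
        assert np.isfinite(cpz).all()


class TestContrasts:
    def test_two_sample_closed_form(self):
        # SZ values (3,4,5) vs HC (1,2,3): t = 2 / sqrt(2/3)
        y = np.array([[3.0], [4.0], [5.0], [1.0], [2.0], [3.0]])
        gd = _manual_design([1, 1, 1, 0, 0, 0])
        mask = np.ones((1, 1, 1), bool)
        gsm = fit_group_contrast((y, mask), gd, "sz_gt_hc")
        assert gsm.t[0, 0, 0] == pytest.approx(2.0 / np.sqrt(2.0 / 3.0), abs=1e-10)

    def test_identical_groups_give_zero_statistic(self):
        y = np.tile([[1.0], [2.0], [3.0]], (2, 1))
        gd = _manual_design([1, 1, 1, 0, 0, 0])
        gsm = fit_group_contrast((y, np.ones((1, 1, 1), bool)), gd, "sz_gt_hc")
        assert gsm.t[0, 0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_flipping_contrast_negates_map(self, rng):
        y = rng.standard_normal((6, 8))
        gd = _manual_design([1, 1, 1, 0, 0, 0])
        mask = np.ones((8, 1, 1), bool)
        a = fit_group_contrast((y, mask), gd, "sz_gt_hc")
        b = fit_group_contrast((y, mask), gd, "hc_gt_sz")
        assert np.allclose(a.t, -b.t, atol=1e-10)
        assert np.allclose(a.z, -b.z, atol=1e-8)


class TestWithinGroup:
    def test_zero_variance_voxels_flagged(self):
        y = np.full((4, 3), 2.0)
        gsm = within_group_map((y, np.ones((3, 1, 1), bool)))
        assert gsm.degenerate.all()
        assert np.all(gsm.t == 0.0)

    def test_null_maps_have_nominal_one_sided_rate(self):
        gen = np.random.default_rng(11)
        y = gen.standard_normal((20, 4000))
        gsm = within_group_map((y, np.ones((4000, 1, 1), bool)))
        frac = (gsm.p_one_sided < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.012)

    def test_two_subject_closed_form(self):
        a, b = 1.0, 2.0
        y = np.array([[a], [b]])
        gsm = within_group_map((y, np.ones((1, 1, 1), bool)))
        mean, sem = (a + b) / 2, np.std([a, b], ddof=1) / np.sqrt(2)
        assert gsm.t[0, 0, 0] == pytest.approx(mean / sem)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            within_group_map((np.ones((1, 2)), np.ones((2, 1, 1), bool)))


def _flood_fill_sizes(supra, conn26=True):
    """Brute-force connected-component sizes."""
    supra = supra.copy()
    sizes = []
    offsets = [
        (di, dj, dk)
        for di in (-1, 0, 1) for dj in (-1, 0, 1) for dk in (-1, 0, 1)
        if (di, dj, dk) != (0, 0, 0)
        and (conn26 or abs(di) + abs(dj) + abs(dk) == 1)
    ]
    nx, ny, nz = supra.shape
    while supra.any():
        start = tuple(np.argwhere(supra)[0])
        stack, comp = [start], 0
        supra[start] = False
        while stack:
            i, j, k = stack.pop()
            comp += 1
            for di, dj, dk in offsets:
                a, b, c = i + di, j + dj, k + dk
                if 0 <= a < nx and 0 <= b < ny and 0 <= c < nz and supra[a, b, c]:
                    supra[a, b, c] = False
                    stack.append((a, b, c))
        sizes.append(comp)
    return sorted(sizes)


class TestClusters:
    def test_two_separated_blobs(self):
        z = np.zeros((10, 10, 4))
        z[1:2, 1:6, 1] = 5.0          # 5 voxels
        z[8, 2:7, 2] = 5.0            # 5 voxels
        table, labels = extract_clusters(z, voxel_p=0.01)
        assert len(table) == 2
        assert list(table["n_voxels"]) == [5, 5]

    def test_corner_touching_blobs_join_under_26_connectivity(self):
        z = np.zeros((6, 6, 6))
        z[1:3, 1:3, 1:3] = 4.0
        z[3:5, 3:5, 3:5] = 4.0        # touches only at the (3,3,3)/(2,2,2) corner
        table26, _ = extract_clusters(z, voxel_p=0.01, connectivity=26)
        table6, _ = extract_clusters(z, voxel_p=0.01, connectivity=6)
        assert len(table26) == 1 and table26["n_voxels"].iloc[0] == 16
        assert len(table6) == 2

    def test_matches_flood_fill_oracle_on_random_maps(self):
        gen = np.random.default_rng(5)
        for _ in range(10):
            z = np.where(gen.random((8, 8, 6)) < 0.3, 5.0, 0.0)
            table, _ = extract_clusters(z, voxel_p=0.01)
            assert sorted(table["n_voxels"]) == _flood_fill_sizes(z > 0)

    def test_subthreshold_map_gives_empty_table(self):
        table, labels = extract_clusters(np.zeros((5, 5, 5)), voxel_p=0.01)
        assert len(table) == 0 and labels.max() == 0


class TestPermutation:
    def _planted_maps(self, seed=2, n_per=3, shape=(6, 6, 2), effect=4.0):
        gen = np.random.default_rng(seed)
        v = int(np.prod(shape))
        y = gen.standard_normal((2 * n_per, v))
        blob = np.zeros(shape, bool)
        blob[1:4, 1:4, 0] = True
        y[:n_per, blob.reshape(-1)] += effect      # SZ rows carry the effect
        mask = np.ones(shape, bool)
        return y, mask, blob

    def test_exhaustive_matches_enumeration_oracle(self):
        from itertools import combinations

        y, mask, _ = self._planted_maps()
        gd = _manual_design([1, 1, 1, 0, 0, 0])
        table, labels, null_max = permutation_cluster_pvalues(
            (y, mask), gd, "sz_gt_hc", voxel_p=0.05, exhaustive=True
        )
        assert len(null_max) == 20                 # C(6,3) assignments
        # oracle: pooled-variance two-sample t per assignment, flood-fill sizes
        tcrit = stats.t.isf(0.05, 4)
        null = []
        for ones in combinations(range(6), 3):
            g = np.zeros(6)
            g[list(ones)] = 1.0
            m1, m0 = y[g == 1].mean(0), y[g == 0].mean(0)
            s2 = (((y[g == 1] - m1) ** 2).sum(0) + ((y[g == 0] - m0) ** 2).sum(0)) / 4
            with np.errstate(divide="ignore", invalid="ignore"):
                t = (m1 - m0) / np.sqrt(s2 * (2 / 3))
            supra = np.zeros(mask.shape, bool)
            supra[mask] = t >= tcrit
            sizes = _flood_fill_sizes(supra)
            null.append(max(sizes) if sizes else 0)
        null = np.array(null)
        for _, row in table.iterrows():
            assert row["p_corr"] == pytest.approx(
                (null >= row["n_voxels"]).mean(), abs=1e-12
            )

    def test_minimum_p_is_one_over_nperm_plus_one(self):
        y, mask, _ = self._planted_maps(seed=7, n_per=6, effect=8.0)
        gd = _manual_design([1] * 6 + [0] * 6)
        table, _, _ = permutation_cluster_pvalues(
            (y, mask), gd, "sz_gt_hc", voxel_p=0.01, n_perm=50, rng_seed=3
        )
        assert table["p_corr"].min() == pytest.approx(1 / 51)

    def test_freedman_lane_reduces_to_label_permutation_without_covariates(self):
        y, mask, _ = self._planted_maps(seed=4, n_per=4, effect=2.0)
        gd = _manual_design([1] * 4 + [0] * 4)
        n_perm, seed = 100, 9
        table, _, null_max = permutation_cluster_pvalues(
            (y, mask), gd, "sz_gt_hc", voxel_p=0.05, n_perm=n_perm, rng_seed=seed
        )
        # manual simple label permutation with the identical rng stream
        gen = np.random.default_rng(seed)
        x = gd.matrix
        pinv = np.linalg.pinv(x)
        cvec = gd.contrasts["sz_gt_hc"]
        tcrit = stats.t.isf(0.05, x.shape[0] - 2)
        cvar = float(cvec @ (pinv @ pinv.T) @ cvec)
        expected = []
        for _ in range(n_perm):
            pi = gen.permutation(8)
            yp = y[pi]
            beta = pinv @ yp
            resid = yp - x @ beta
            se2 = (resid**2).sum(0) / (8 - 2) * cvar
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(se2 <= 0, 0.0, (cvec @ beta) / np.sqrt(se2))
            supra = np.zeros(mask.shape, bool)
            supra[mask] = t >= tcrit
            sizes = _flood_fill_sizes(supra)
            expected.append(max(sizes) if sizes else 0)
        assert np.array_equal(null_max, np.array(expected))

    def test_p_values_monotone_in_cluster_size(self):
        y, mask, _ = self._planted_maps(seed=12, n_per=5, effect=3.0)
        gd = _manual_design([1] * 5 + [0] * 5)
        table, _, _ = permutation_cluster_pvalues(
            (y, mask), gd, "sz_gt_hc", voxel_p=0.10, n_perm=99, rng_seed=1
        )
        if len(table) >= 2:
            assert (table.sort_values("n_voxels", ascending=False)["p_corr"]
                    .is_monotonic_increasing)
        assert ((table["p_corr"] > 0) & (table["p_corr"] <= 1)).all()

    def test_too_few_permutations_refused(self):
        y, mask, _ = self._planted_maps()
        gd = _manual_design([1, 1, 1, 0, 0, 0])
        with pytest.raises(ValueError, match="n_perm"):
            permutation_cluster_pvalues((y, mask), gd, "sz_gt_hc", n_perm=10,
                                        rng_seed=0)
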