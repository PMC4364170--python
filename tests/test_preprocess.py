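"""Signal conditioning: discard, smoothing, band-pass, motion QC, design."""

import numpy as np
import pytest

from cbfc.preprocess import (
    FWHM_TO_SIGMA,
    BoldSeries,
    FilterSpec,
    MotionParams,
    bandpass_gain,
    bandpass_matrix,
    bandpass_temporal,
    build_first_level_design,
    drop_initial_volumes,
    extract_mean_timecourse,
    mean_abs_displacement,
    rigid_matrix,
    rms_displacement,
    sigma_from_cutoff,
    smooth_spatial,
)


def _bold(data, tr=2.5):
    return BoldSeries(np.asarray(data, dtype=float), tr)


class TestDropVolumes:
    def test_study_count_240_minus_4(self, rng):
        b = _bold(rng.standard_normal((2, 2, 2, 240)))
        m = MotionParams(rng.standard_normal((240, 6)))
        b2, m2 = drop_initial_volumes(b, 4, m)
        assert b2.n_volumes == 236 and m2.n_volumes == 236
        assert np.array_equal(b2.data, b.data[..., 4:])

    def test_zero_drop_is_identity(self, rng):
        b = _bold(rng.standard_normal((2, 2, 2, 10)))
        assert np.array_equal(drop_initial_volumes(b, 0).data, b.data)

    def test_dropping_all_volumes_fails(self, rng):
        b = _bold(rng.standard_normal((2, 2, 2, 4)))
        with pytest.raises(ValueError):
            drop_initial_volumes(b, 4)


class TestSmoothing:
    def test_constant_volume_unchanged(self):
        b = _bold(np.full((8, 8, 8, 3), 5.0))
        out = smooth_spatial(b, fwhm_mm=6, voxel_mm=2)
        assert np.allclose(out.data, 5.0)

    def test_impulse_spreads_but_conserves_sum(self):
        data = np.zeros((11, 11, 11, 2))
        data[5, 5, 5, 0] = 1.0
        out = smooth_spatial(_bold(data), fwhm_mm=6, voxel_mm=2)
        assert out.data.max() < 1.0
        assert out.data[..., 0].sum() == pytest.approx(1.0, rel=1e-6)

    def test_sigma_in_voxels_from_fwhm(self):
        # 6 mm FWHM at 2 mm voxels: sigma = 6 / (2.3548 * 2) ~ 1.274 voxels
        assert 6.0 * FWHM_TO_SIGMA / 2.0 == pytest.approx(1.2739827, abs=1e-6)

    def test_nonpositive_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_spatial(_bold(np.zeros((3, 3, 3, 2))), fwhm_mm=0)


class TestSigmaFromCutoff:
    @pytest.mark.parametrize(
        "f, tr, expected",
        [(0.08, 2.5, 2.5), (0.009, 2.5, 22.2), (0.1, 1.0, 5.0)],
    )
    def test_printed_sigma_values(self, f, tr, expected):
        assert round(sigma_from_cutoff(f, tr), 1) == expected

    def test_cutoff_at_nyquist_warns(self):
        with pytest.warns(UserWarning):
            sigma_from_cutoff(0.2, 2.5)

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            sigma_from_cutoff(0.0, 2.5)


class TestBandpass:
    def test_constant_series_maps_to_zero(self):
        fs = FilterSpec(tr_seconds=2.5)
        x = np.full((100, 3), 7.0)
        assert np.allclose(bandpass_temporal(x, fs), 0.0, atol=1e-10)

    def test_linearity(self, rng):
        fs = FilterSpec(tr_seconds=2.5)
        x, y = rng.standard_normal((2, 120))
        lhs = bandpass_temporal(2.0 * x + 3.0 * y, fs)
        rhs = 2.0 * bandpass_temporal(x, fs) + 3.0 * bandpass_temporal(y, fs)
        assert np.allclose(lhs, rhs, atol=1e-10)

    @staticmethod
    def _empirical_gain(f, fs, n=236):
        t = np.arange(n) * fs.tr_seconds
        x = np.sin(2 * np.pi * f * t)
        y = bandpass_matrix(n, fs) @ x
        sl = slice(n // 4, 3 * n // 4)       # away from truncation boundaries
        design = np.column_stack(
            [np.sin(2 * np.pi * f * t[sl]), np.cos(2 * np.pi * f * t[sl]),
             np.ones(sl.stop - sl.start)]
        )
        coef, *_ = np.linalg.lstsq(design, y[sl], rcond=None)
        return float(np.hypot(coef[0], coef[1]))

    def test_in_band_probe_matches_transfer_oracle(self):
        # Gaussian transfer product at 0.03 Hz gives ~0.50 amplitude
        fs = FilterSpec(tr_seconds=2.5)
        g = self._empirical_gain(0.03, fs)
        assert g == pytest.approx(0.4996, abs=0.01)
        assert g == pytest.approx(float(bandpass_gain(0.03, fs)), rel=0.02)

    def test_above_cutoff_probe_is_suppressed(self):
        fs = FilterSpec(tr_seconds=2.5)
        assert self._empirical_gain(0.19, fs) < 0.1

    def test_transfer_function_across_band(self):
        # empirical response tracks the analytic Gaussian product
        fs = FilterSpec(tr_seconds=2.5)
        for f in (0.005, 0.009, 0.02, 0.05, 0.08, 0.12, 0.19):
            emp = self._empirical_gain(f, fs)
            ana = float(bandpass_gain(f, fs))
            if ana >= 0.01:
                assert abs(emp - ana) / ana < 0.10
            else:
                assert emp < 0.01

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec(f_low_hz=0.1, f_high_hz=0.05, tr_seconds=2.5)


class TestDisplacement:
    def test_no_motion_gives_zero(self):
        m = MotionParams(np.tile([0.01, 0.0, 0.02, 1.0, 2.0, 3.0], (5, 1)))
        assert mean_abs_displacement(m) == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation_equals_step_size(self):
        params = np.cumsum(np.tile([0, 0, 0, 1.0, 0, 0], (6, 1)), axis=0)
        assert mean_abs_displacement(MotionParams(params)) == pytest.approx(1.0)

    def test_rotation_matches_monte_carlo_ball_oracle(self):
        p1 = np.zeros(6)
        p2 = np.array([0.01, -0.02, 0.015, 0.3, -0.1, 0.2])
        closed = rms_displacement(rigid_matrix(p1), rigid_matrix(p2), 80.0)
        gen = np.random.default_rng(42)
        pts = gen.standard_normal((100000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= 80.0 * gen.random(100000)[:, None] ** (1 / 3)  # uniform in ball
        rel = rigid_matrix(p2) @ np.linalg.inv(rigid_matrix(p1))
        moved = pts @ rel[:3, :3].T + rel[:3, 3]
        mc = np.sqrt(np.mean(np.sum((moved - pts) ** 2, axis=1)))
        assert closed == pytest.approx(mc, rel=0.01)

    def test_invariant_to_global_rigid_offset(self):
        # only relative motion counts: right-composing a fixed transform
        # onto every volume leaves the displacement unchanged
        g = rigid_matrix([0.3, -0.2, 0.1, 5.0, -3.0, 2.0])
        t1 = rigid_matrix([0.01, 0.0, -0.01, 0.5, 0.2, -0.3])
        t2 = rigid_matrix([0.015, -0.005, 0.0, 0.7, 0.1, -0.2])
        assert rms_displacement(t1 @ g, t2 @ g) == pytest.approx(
            rms_displacement(t1, t2), rel=1e-9
        )

    def test_single_volume_rejected(self):
        with pytest.raises(ValueError):
            mean_abs_displacement(MotionParams(np.zeros((1, 6))))


class TestTimecourse:
    def test_mean_of_two_voxels(self):
        data = np.zeros((2, 1, 1, 2))
        data[0, 0, 0] = (1, 2)
        data[1, 0, 0] = (3, 4)
        mask = np.ones((2, 1, 1), bool)
        assert np.allclose(extract_mean_timecourse(_bold(data), mask), [2, 3])

    def test_single_voxel_mask(self, rng):
        data = rng.standard_normal((3, 3, 3, 5))
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 2, 0] = True
        assert np.allclose(extract_mean_timecourse(_bold(data), mask), data[1, 2, 0])

    def test_partition_means_recombine_to_global_mean(self, rng):
        data = rng.standard_normal((4, 4, 2, 6))
        b = _bold(data)
        m1 = np.zeros((4, 4, 2), bool)
        m1[:2] = True
        m2 = ~m1
        combined = (
            m1.sum() * extract_mean_timecourse(b, m1)
            + m2.sum() * extract_mean_timecourse(b, m2)
        ) / (m1.sum() + m2.sum())
        assert np.allclose(combined, data.reshape(-1, 6).mean(axis=0))

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError):
            extract_mean_timecourse(
                _bold(rng.standard_normal((2, 2, 2, 3))), np.zeros((2, 2, 2), bool)
            )


class TestDesign:
    def test_full_rank_ten_columns(self, rng):
        n = 50
        d = build_first_level_design(
            rng.standard_normal(n), rng.standard_normal(n), rng.standard_normal(n),
            MotionParams(rng.standard_normal((n, 6))),
        )
        assert d.matrix.shape == (n, 10)
        assert np.linalg.matrix_rank(d.matrix) == 10
        assert d.names[0] == "seed" and d.names[-1] == "intercept"

    def test_duplicated_motion_column_raises_naming_columns(self, rng):
        n = 40
        motion = rng.standard_normal((n, 6))
        motion[:, 1] = motion[:, 0]
        with pytest.raises(ValueError, match="rot"):
            build_first_level_design(
                rng.standard_normal(n), rng.standard_normal(n),
                rng.standard_normal(n), MotionParams(motion),
            )

    def test_non_intercept_columns_are_centered(self, rng):
        n = 30
        d = build_first_level_design(
            rng.standard_normal(n) + 5.0, rng.standard_normal(n) - 2.0,
            rng.standard_normal(n), MotionParams(rng.standard_normal((n, 6))),
        )
        assert np.allclose(d.matrix[:, :-1].mean(axis=0), 0.0, atol=1e-12)
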