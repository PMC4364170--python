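"""Voxelwise first-level GLM: cerebellar voxels on the seed regressor.

Each cerebellar voxel's preprocessed series is regressed on the first-level
design (seed + nuisance + intercept) by ordinary least squares; the seed
beta and its classical t statistic are converted to z through the
quantile transform z = Phi^-1(F_t(t; dof)).  No prewhitening is applied:
the temporal band-pass already colours the noise, and validity of the
group stage rests on permutation, not on first-level degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .preprocess import BoldSeries, DesignMatrix

Z_CLAMP = 38.0  # |z| beyond this is numerically indistinguishable from the tail


@dataclass
class FCMap:
    """Per-subject, per-network connectivity map over the cerebellum mask."""

    beta: np.ndarray            # 3D seed-beta map (0 outside mask)
    t: np.ndarray               # 3D t map
    z: np.ndarray               # 3D z map
    mask: np.ndarray            # cerebellum mask the maps are defined on
    dof: int                    # residual degrees of freedom
    network_id: str = ""
    subject_id: str = ""
    zero_variance: np.ndarray = field(default=None)  # flagged degenerate voxels
    rss: np.ndarray = field(default=None)            # residual sum of squares

    def masked(self, which: str = "z") -> np.ndarray:
        """1D vector of the chosen statistic over the mask voxels."""
        return getattr(self, which)[self.mask]


def t_to_z(t, dof: int):
    """Map t statistics to standard-normal z by quantile transform.

    Sign-preserving and monotone; uses the survival function on the
    positive branch for tail precision.  Values beyond |z| = 38 are clamped
    with a warning (the double-precision tail limit).
    """
    if dof < 1:
        raise ValueError("dof must be >= 1")
    t = np.asarray(t, dtype=float)
    p_tail = stats.t.sf(np.abs(t), dof)
    with np.errstate(divide="ignore"):
        z = -special.ndtri(p_tail)
    z = np.where(np.isneginf(z), np.inf, z)  # ndtri(0) -> -inf means extreme tail
    if np.any(np.abs(z) > Z_CLAMP) or np.any(np.isinf(z)):
        warnings.warn("extreme t statistics clamped at |z| = 38")
    z = np.clip(z, None, Z_CLAMP)
    out = np.sign(t) * z
    return out if out.ndim else float(out)


def fit_voxelwise_glm(
    bold: BoldSeries,
    mask: np.ndarray,
    design: DesignMatrix,
    network_id: str = "",
    subject_id: str = "",
) -> FCMap:
    """OLS fit of every mask voxel's series on the design; seed beta, t, z.

    Residuals are orthogonal to the design columns by construction.  Voxels
    with zero residual variance get t = 0 and are flagged in
    ``zero_variance``.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != bold.data.shape[:3]:
        raise ValueError("mask grid does not match BOLD grid")
    x = design.matrix
    n, p = x.shape
    if n != bold.n_volumes:
        raise ValueError("design rows must equal BOLD time points")
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("design matrix is rank deficient")
    dof = n - p
    if dof < 1:
        raise ValueError("no residual degrees of freedom")

    y = bold.data[mask].T                      # (time, voxels)
    pinv = np.linalg.pinv(x)
    beta = pinv @ y                            # (p, voxels)
    resid = y - x @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    xtx_inv = pinv @ pinv.T                    # (X'X)^-1 via pinv = (X'X)^-1 X'
    j = design.seed_index
    se2 = rss / dof * xtx_inv[j, j]
    zero_var = se2 <= np.finfo(float).eps * np.maximum(1.0, np.abs(beta[j]))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_var, 0.0, beta[j] / np.sqrt(se2))
    z = t_to_z(t, dof)

    def embed(v):
        out = np.zeros(mask.shape)
        out[mask] = v
        return out

    return FCMap(
        beta=embed(beta[j]),
        t=embed(t),
        z=embed(np.atleast_1d(z)),
        mask=mask,
        dof=dof,
        network_id=network_id,
        subject_id=subject_id,
        zero_variance=embed(zero_var.astype(float)).astype(bool),
        rss=embed(rss),
    )
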