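"""Correlation of cluster-wise connectivity with clinical symptom scales.

For every network contrast with significant clusters, the mean
preprocessed BOLD series over the union of the contrast's clusters is
correlated (Pearson) with the cortical seed series, giving one
connectivity value per subject.  These values are then correlated with the
five symptom scales (SAPS, SANS, YMRS, MADRS, PSYRATS-AH) over the
patients, with pairwise-complete handling of missing scores and Bonferroni
control over the scale x contrast family (5 x 7 = 35 tests in the study
configuration, per-test alpha 0.05 / 35 ~ 0.00143).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import BoldSeries, extract_mean_timecourse

logger = logging.getLogger(__name__)

SYMPTOM_SCALES = ["SAPS", "SANS", "YMRS", "MADRS", "PSYRATS_AH"]


def subject_cluster_fc(bold: BoldSeries, cluster_masks, seed_tc) -> float:
    """Pearson r between the combined-cluster mean series and the seed series.

    ``cluster_masks`` is one binary mask or a sequence of masks; all
    clusters within a contrast are combined by union before averaging.
    Returns NaN (with a warning) if either series has zero variance.
    """
    masks = cluster_masks if isinstance(cluster_masks, (list, tuple)) else [cluster_masks]
    union = np.zeros(bold.data.shape[:3], dtype=bool)
    for m in masks:
        union |= np.asarray(m).astype(bool)
    if not union.any():
        raise ValueError("cluster masks are empty")
    tc = extract_mean_timecourse(bold, union)
    seed_tc = np.asarray(seed_tc, dtype=float)
    if np.std(tc) == 0 or np.std(seed_tc) == 0:
        logger.warning("zero-variance series: cluster FC undefined")
        return float("nan")
    return float(stats.pearsonr(tc, seed_tc).statistic)


def bonferroni_threshold(alpha: float = 0.05, m: int = 35, paper_compat: bool = False) -> float:
    """Per-test alpha controlling the family of ``m`` tests at ``alpha``.

    ``paper_compat`` applies the rounded p < 0.001 convention some reports
    use for 35 tests instead of the exact 0.05 / 35.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if paper_compat:
        return 1e-3
    return alpha / m


def correlate_scales(
    fc_values: pd.DataFrame,
    scores: pd.DataFrame,
    alpha: float = 0.05,
    m: int | None = None,
    paper_compat: bool = False,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Correlate per-subject FC values with symptom scales, cell by cell.

    ``fc_values``: subjects x network-contrasts; ``scores``: subjects x
    scales, aligned on index, NaN for missing.  Each (scale, contrast) cell
    gets a pairwise-complete Pearson r, its two-sided p, and the n used;
    cells with fewer than ``min_pairs`` complete pairs are marked
    not-computable (NaN r/p).  ``m`` defaults to the full matrix size.

    Returns a long table (scale, contrast, r, p, n, significant).
    """
    scales = list(scores.columns)
    contrasts = list(fc_values.columns)
    if m is None:
        m = len(scales) * len(contrasts)
    thr = bonferroni_threshold(alpha, m, paper_compat)
    rows = []
    for scale in scales:
        for contrast in contrasts:
            s = pd.to_numeric(scores[scale], errors="coerce")
            f = pd.to_numeric(fc_values[contrast], errors="coerce")
            ok = s.notna() & f.notna()
            n = int(ok.sum())
            if n < min_pairs:
                rows.append({"scale": scale, "contrast": contrast,
                             "r": np.nan, "p": np.nan, "n": n, "significant": False})
                continue
            res = stats.pearsonr(f[ok], s[ok])
            rows.append({"scale": scale, "contrast": contrast,
                         "r": float(res.statistic), "p": float(res.pvalue),
                         "n": n, "significant": bool(res.pvalue < thr)})
    return pd.DataFrame(rows)
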