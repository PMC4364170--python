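"""Overlap of thresholded group maps with a canonical cerebellar parcellation.

Positive voxels are those inside the canonical single-network cerebellar
map; negative voxels are cerebellar voxels outside it.  True positives are
group-map voxels intersecting the canonical map, false positives are
group-map voxels in the negative territory, and true negatives are the
negative voxels minus the false positives.  Accuracy is
(TP + TN) / (P + N), sensitivity TP / P, specificity TN / N.  A
winner-take-all labeller assigns each cerebellar voxel to the network with
the largest statistic, the construction used for canonical cerebellar
parcellations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .seeds import LabelVolume

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    """Voxel confusion counts against a canonical map."""

    tp: int
    fp: int
    tn: int
    fn: int
    p: int
    n: int

    def __post_init__(self) -> None:
        if not (self.tp <= self.p and self.fp <= self.n):
            raise ValueError("inconsistent confusion counts")
        if self.tn != self.n - self.fp or self.fn != self.p - self.tp:
            raise ValueError("tn/fn do not match complements")


def binarize_map(stat_map, cerebellum_mask, alpha: float = 0.05) -> np.ndarray:
    """One-sided p < alpha threshold of a z map, restricted to the cerebellum.

    ``stat_map`` may be a 3D z array or an object with ``z`` and ``mask``
    attributes (a group stat map).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie strictly inside (0, 1)")
    z = getattr(stat_map, "z", stat_map)
    z = np.asarray(z, dtype=float)
    zcrit = stats.norm.isf(alpha)
    return (z >= zcrit) & np.asarray(cerebellum_mask).astype(bool)


def confusion_counts(group_mask, canonical_mask, cerebellum_mask) -> ConfusionCounts:
    """Confusion counts of a binarized group map against the canonical map.

    Group voxels outside the cerebellum are ignored; the canonical map must
    lie inside the cerebellum.
    """
    g = np.asarray(group_mask).astype(bool)
    can = np.asarray(canonical_mask).astype(bool)
    cb = np.asarray(cerebellum_mask).astype(bool)
    if g.shape != can.shape or can.shape != cb.shape:
        raise ValueError("masks must share one grid")
    if np.any(can & ~cb):
        raise ValueError("canonical map must be contained in the cerebellum mask")
    g = g & cb
    p = int(can.sum())
    n = int((cb & ~can).sum())
    tp = int((g & can).sum())
    fp = int((g & cb & ~can).sum())
    return ConfusionCounts(tp=tp, fp=fp, tn=n - fp, fn=p - tp, p=p, n=n)


def overlap_metrics(cc: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity and specificity from confusion counts.

    accuracy = (TP + TN) / (P + N); sensitivity = TP / P;
    specificity = TN / N.  A zero P or N leaves the affected metric NaN
    with a warning.
    """
    out: dict[str, float] = {}
    out["accuracy"] = (
        (cc.tp + cc.tn) / (cc.p + cc.n) if (cc.p + cc.n) > 0 else float("nan")
    )
    if cc.p > 0:
        out["sensitivity"] = cc.tp / cc.p
    else:
        logger.warning("no positive voxels: sensitivity undefined")
        out["sensitivity"] = float("nan")
    if cc.n > 0:
        out["specificity"] = cc.tn / cc.n
    else:
        logger.warning("no negative voxels: specificity undefined")
        out["specificity"] = float("nan")
    return out


def dice(mask_a, mask_b) -> float:
    """Dice coefficient of two binary masks (an auxiliary overlap measure)."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else float("nan")


def winner_take_all(stat_maps: dict, mask, affine=None) -> tuple[LabelVolume, int]:
    """Label each mask voxel with the network of maximal statistic.

    ``stat_maps`` maps network id (int) -> 3D statistic array.  Exact ties
    are broken toward the lowest network id and counted; the count is
    returned alongside the label volume.
    """
    if not stat_maps:
        raise ValueError("need at least one network statistic map")
    mask = np.asarray(mask).astype(bool)
    ids = sorted(stat_maps)
    stack = np.stack([np.asarray(stat_maps[i], dtype=float) for i in ids], axis=0)
    best = np.argmax(stack, axis=0)          # argmax takes the first (lowest id) on ties
    n_ties = int(
        ((stack == stack.max(axis=0, keepdims=True)).sum(axis=0) > 1)[mask].sum()
    )
    if n_ties:
        logger.info("winner-take-all: %d tied voxels broken toward lowest id", n_ties)
    out = np.zeros(mask.shape, dtype=np.int32)
    out[mask] = np.asarray(ids, dtype=np.int32)[best[mask]]
    labels = LabelVolume(out, np.eye(4) if affine is None else affine,
                         {int(i): str(i) for i in ids})
    return labels, n_ties
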