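"""Cortical seed construction from a 17-network parcellation.

The analysis seeds are built from an integer label volume holding the
17-network cortical parcellation: the volume is resampled to the analysis
grid with nearest-neighbour interpolation, split into one binary mask per
network, the two limbic networks (temporal pole, orbitofrontal cortex) are
merged into a single seed, networks with minimal cerebellar representation
(<= 30 voxels in the cerebellar network map) are excluded, and each
retained mask is eroded by one voxel layer to avoid boundary contamination.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Network names for the 17-network cortical parcellation (ids 1-17).
NETWORK_NAMES_17 = {
    1: "visual peripheral",
    2: "visual central",
    3: "somatomotor A",
    4: "somatomotor B",
    5: "dorsal attention A",
    6: "dorsal attention B",
    7: "ventral attention",
    8: "salience",
    9: "temporal pole",
    10: "orbitofrontal",
    11: "control C",
    12: "control A",
    13: "control B",
    14: "auditory",
    15: "default mode C",
    16: "default mode A",
    17: "default mode B",
}

#: Default pair of limbic networks merged into one seed.
LIMBIC_MERGE_IDS = (9, 10)

#: Cerebellar-representation cutoff (voxels); networks at or below are dropped.
MIN_CEREBELLAR_VOXELS = 30


@dataclass
class LabelVolume:
    """3D integer label grid with an affine and an id -> name table.

    Background is 0.  ``affine`` maps voxel indices (i, j, k, 1) to world
    coordinates in mm.
    """

    data: np.ndarray
    affine: np.ndarray
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("label data must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label data must be integer")
        if self.data.min() < 0:
            raise ValueError("labels must be nonnegative")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def counts(self) -> dict[int, int]:
        """Voxel count per nonzero label."""
        ids, n = np.unique(self.data[self.data > 0], return_counts=True)
        return dict(zip(ids.tolist(), n.tolist()))

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.int16), self.affine)

    @classmethod
    def from_nifti(cls, path, labels: dict[int, str] | None = None) -> "LabelVolume":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        return cls(np.rint(data).astype(np.int32), img.affine, labels or {})


@dataclass
class Seed:
    """One retained analysis seed (possibly a merger of several networks)."""

    seed_id: str
    member_ids: tuple[int, ...]
    name: str
    mask: np.ndarray            # eroded binary mask on the analysis grid
    voxel_count: int            # voxels in the eroded mask
    cerebellar_count: int       # voxels in the cerebellar network map


@dataclass
class SeedSet:
    """Retained, eroded network seeds plus the full selection roster."""

    seeds: list[Seed]
    roster: "object"            # pandas.DataFrame with per-network bookkeeping

    def __iter__(self):
        return iter(self.seeds)

    def __len__(self) -> int:
        return len(self.seeds)

    def __getitem__(self, seed_id: str) -> Seed:
        for s in self.seeds:
            if s.seed_id == seed_id:
                return s
        raise KeyError(seed_id)


def resample_labels_nearest(lv: LabelVolume, target_shape, target_affine) -> LabelVolume:
    """Resample a label volume onto a target grid by nearest neighbour.

    Each target voxel takes the label of the source voxel whose center is
    nearest to the target voxel center; coordinates are compared through the
    two affines.  Target voxels mapping outside the source grid become
    background.  The output label set is a subset of the input label set.
    """
    target_affine = np.asarray(target_affine, dtype=float)
    if abs(np.linalg.det(target_affine)) < 1e-12:
        raise ValueError("target affine must be invertible")
    nx, ny, nz = target_shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=0).reshape(4, -1)
    # target voxel -> world -> source voxel (continuous)
    src = np.linalg.inv(lv.affine) @ target_affine @ vox
    # round half up for a deterministic nearest-center rule
    idx = np.floor(src[:3] + 0.5).astype(np.int64)
    inside = np.all(idx >= 0, axis=0)
    for ax, n in enumerate(lv.shape):
        inside &= idx[ax] < n
    out = np.zeros(idx.shape[1], dtype=lv.data.dtype)
    out[inside] = lv.data[idx[0, inside], idx[1, inside], idx[2, inside]]
    return LabelVolume(out.reshape(nx, ny, nz), target_affine, dict(lv.labels))


def split_labels(lv: LabelVolume) -> dict[int, np.ndarray]:
    """Split a label volume into one binary mask per nonzero label."""
    return {int(i): lv.data == i for i in np.unique(lv.data) if i != 0}


def merge_labels(masks: dict[int, np.ndarray], ids=LIMBIC_MERGE_IDS) -> np.ndarray:
    """Union of the masks for ``ids`` (the limbic merge)."""
    missing = [i for i in ids if i not in masks]
    if missing:
        raise KeyError(f"cannot merge: missing network ids {missing}")
    out = np.zeros_like(next(iter(masks.values())), dtype=bool)
    for i in ids:
        out |= masks[i].astype(bool)
    return out


def select_networks(
    cerebellar_counts: dict[int, int],
    threshold: int = MIN_CEREBELLAR_VOXELS,
    merge_ids=LIMBIC_MERGE_IDS,
) -> list[tuple[int, ...]]:
    """Select analysis networks by cerebellar representation.

    Networks with ``count <= threshold`` cerebellar voxels are excluded.
    The merge pair (by default the two limbic networks) is counted once: if
    both members are retained they appear as a single merged entry whose
    cerebellar count is the sum of the members'.

    Returns a list of member-id tuples, singletons for unmerged networks.
    """
    if any(c < 0 for c in cerebellar_counts.values()):
        raise ValueError("cerebellar counts must be nonnegative")
    retained = [i for i, c in sorted(cerebellar_counts.items()) if c > threshold]
    if not retained:
        warnings.warn("no networks retained: all cerebellar counts at/below threshold")
        return []
    roster: list[tuple[int, ...]] = []
    merge_members = tuple(i for i in merge_ids if i in retained)
    merged_emitted = False
    for i in retained:
        if i in merge_members:
            if len(merge_members) > 1:
                if not merged_emitted:
                    roster.append(merge_members)
                    merged_emitted = True
                continue
        roster.append((i,))
    return roster


def erode_one_layer(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Erode a binary mask by one voxel layer.

    With the default full 3x3x3 structuring element a voxel survives iff it
    and all 26 neighbours are inside the mask (out-of-grid counts as
    outside).  ``connectivity=6`` uses the face-neighbour cross instead.
    """
    mask = np.asarray(mask).astype(bool)
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    return ndimage.binary_erosion(mask, structure=structure, border_value=0)


def build_seed_set(
    cortical: LabelVolume,
    cerebellar: LabelVolume,
    threshold: int = MIN_CEREBELLAR_VOXELS,
    merge_ids=LIMBIC_MERGE_IDS,
    connectivity: int = 26,
) -> SeedSet:
    """Full seed-construction flow: split, merge, select, erode.

    ``cortical`` and ``cerebellar`` must already live on their analysis
    grids (use :func:`resample_labels_nearest` first if not).  Selection is
    driven by the cerebellar label counts; the retained cortical masks are
    eroded by one layer.
    """
    import pandas as pd

    masks = split_labels(cortical)
    cb_counts = cerebellar.counts()
    all_ids = sorted(set(masks) | set(cb_counts))
    roster_sel = select_networks(
        {i: cb_counts.get(i, 0) for i in all_ids}, threshold, merge_ids
    )
    seeds: list[Seed] = []
    for members in roster_sel:
        if len(members) == 1:
            raw = masks.get(members[0])
            if raw is None:
                raise KeyError(f"network {members[0]} missing from cortical labels")
            name = cortical.labels.get(members[0], NETWORK_NAMES_17.get(members[0], str(members[0])))
            seed_id = str(members[0])
        else:
            raw = merge_labels(masks, members)
            name = "limbic (merged " + "+".join(map(str, members)) + ")"
            seed_id = "+".join(map(str, members))
        eroded = erode_one_layer(raw, connectivity)
        cb = int(sum(cb_counts.get(i, 0) for i in members))
        seeds.append(Seed(seed_id, tuple(members), name, eroded, int(eroded.sum()), cb))
        if eroded.sum() == 0:
            logger.warning("seed %s eroded to empty mask", seed_id)
    rows = []
    retained_members = {i for s in seeds for i in s.member_ids}
    for i in all_ids:
        rows.append(
            {
                "network_id": i,
                "name": cortical.labels.get(i, NETWORK_NAMES_17.get(i, str(i))),
                "cerebellar_voxels": cb_counts.get(i, 0),
                "retained": i in retained_members,
            }
        )
    return SeedSet(seeds=seeds, roster=pd.DataFrame(rows))
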