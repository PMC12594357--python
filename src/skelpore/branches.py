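"""Skeleton voxel classification and segmentation into maximal simple branches.

A skeleton voxel is *ending* (one 26-neighbor in the skeleton), *simple*
(exactly two) or *interior* (more than two).  A branch is a maximal
26-connected set of simple voxels; ending and interior voxels sit at branch
extremities.  Every skeleton voxel ends up owning exactly one branch id, so
branches partition the skeleton — which the region partition downstream
relies on.

Ownership rules for the non-simple voxels (the classification itself leaves
them unassigned):

* an ending voxel joins its unique adjacent branch;
* an interior (junction) voxel joins the adjacent branch with the smallest
  id; clusters are absorbed iteratively from their assigned neighbors;
* skeleton components with no simple voxel at all (isolated voxels,
  two-voxel components, tiny "+" junctions) each form their own branch.

Final branch ids are assigned in lexicographic order of each branch's
minimal voxel, for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from skelpore.skeleton import Skeleton
from skelpore.volumes import CONN26

__all__ = ["SkeletonClassification", "BranchSet", "classify_voxels", "segment_branches"]

ENDING, SIMPLE, INTERIOR = 1, 2, 3


@dataclass(frozen=True)
class SkeletonClassification:
    """Per-voxel skeleton classes.

    ``kind`` is 0 outside the skeleton, else ENDING (1) / SIMPLE (2) /
    INTERIOR (3).  Isolated skeleton voxels (no neighbor) are classed
    ending.  ``neighbor_counts`` holds the raw 26-neighbor counts.
    """

    kind: np.ndarray
    neighbor_counts: np.ndarray

    def count(self, which: int) -> int:
        return int((self.kind == which).sum())

    @property
    def n_ending(self) -> int:
        return self.count(ENDING)

    @property
    def n_simple(self) -> int:
        return self.count(SIMPLE)

    @property
    def n_interior(self) -> int:
        return self.count(INTERIOR)


@dataclass(frozen=True)
class BranchSet:
    """Partition of the skeleton into branches.

    ``labels`` is 0 off the skeleton and a 1-based branch id on it;
    ``branches`` maps id -> (n, 3) voxel coordinate array.
    """

    labels: np.ndarray
    branches: dict[int, np.ndarray]

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    @property
    def ids(self) -> list[int]:
        return sorted(self.branches)


def classify_voxels(skeleton: Skeleton) -> SkeletonClassification:
    """Classify each skeleton voxel by its 26-neighbor count in the skeleton."""
    mask = skeleton.mask
    counts = ndimage.convolve(mask.astype(np.int16), CONN26.astype(np.int16), mode="constant") - 1
    counts[~mask] = 0
    kind = np.zeros(mask.shape, dtype=np.int8)
    kind[mask & (counts <= 1)] = ENDING
    kind[mask & (counts == 2)] = SIMPLE
    kind[mask & (counts > 2)] = INTERIOR
    return SkeletonClassification(kind=kind, neighbor_counts=counts)


def _order_labels_by_min_voxel(labels: np.ndarray, n: int) -> np.ndarray:
    """Return a relabeling table (old -> new) ranking labels by the
    lexicographically smallest member voxel (C-order flat index)."""
    flat = labels.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    idx = np.flatnonzero(flat)
    # idx is ascending, so the first occurrence per label is its minimum
    lab = flat[idx]
    uniq, first_pos = np.unique(lab, return_index=True)
    first[uniq] = idx[first_pos]
    order = np.argsort(first[1 : n + 1], kind="stable") + 1
    table = np.zeros(n + 1, dtype=np.int32)
    table[order] = np.arange(1, n + 1)
    return table


def segment_branches(skeleton: Skeleton, classification: SkeletonClassification | None = None) -> BranchSet:
    """Segment the skeleton into branches (see module docstring for rules)."""
    if classification is None:
        classification = classify_voxels(skeleton)
    mask = skeleton.mask
    kind = classification.kind

    simple_mask = kind == SIMPLE
    labels32, n = ndimage.label(simple_mask, structure=CONN26, output=np.int32)
    labels = labels32.astype(np.int32)
    if n:
        labels = _order_labels_by_min_voxel(labels, n)[labels]

    # absorb non-simple voxels into adjacent branches, smallest id first
    unassigned = mask & (labels == 0)
    while unassigned.any():
        coords = np.argwhere(unassigned)  # lexicographic order
        changed = False
        for i, j, k in coords:
            patch = labels[
                max(0, i - 1) : i + 2, max(0, j - 1) : j + 2, max(0, k - 1) : k + 2
            ]
            pos = patch[patch > 0]
            if pos.size:
                labels[i, j, k] = int(pos.min())
                changed = True
        if not changed:
            break
        unassigned = mask & (labels == 0)

    # leftover components contain no simple voxel anywhere: own branches
    leftover = mask & (labels == 0)
    if leftover.any():
        extra, n_extra = ndimage.label(leftover, structure=CONN26, output=np.int32)
        labels[leftover] = extra[leftover] + n
        n += n_extra

    # final ids in lexicographic order of each branch's minimal voxel
    labels = _order_labels_by_min_voxel(labels, n)[labels]

    coords = np.argwhere(labels > 0)
    ids = labels[coords[:, 0], coords[:, 1], coords[:, 2]]
    branches = {int(b): coords[ids == b] for b in np.unique(ids)}
    return BranchSet(labels=labels, branches=branches)
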