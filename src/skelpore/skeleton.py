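"""Curve skeletonization by homotopic thinning, with topology diagnostics.

The skeleton of the pore set S is obtained by iterated erosion passes.  A
voxel is deleted when all four conditions hold:

(i)   it lies on the boundary B of S (some 26-neighbor is background);
(ii)  it is not an ending point (it has at least two 26-neighbors);
(iii) its removal preserves the Euler characteristic;
(iv)  its removal preserves the number of 26-connected components.

Conditions (iii)/(iv) are evaluated on the 3x3x3 neighborhood: because every
cell (vertex/edge/face/octant) of a voxel is shared only with its
26-neighbors, the local Euler change equals the global one exactly, and the
local component test is the classical simple-point connectivity condition.
The conjunction is checked against a global brute-force oracle in the test
suite.

Each pass collects the current boundary voxels, orders them by increasing
distance to the original boundary (lexicographic (i, j, k) order within a
distance shell) and attempts deletions sequentially, re-testing against the
already updated volume; passes repeat until a fixed point is reached
(idempotence).  The shell ordering keeps the erosion front centered —
visiting voxels in raw lexicographic order can strand a voxel of the
eventual skeleton at degree one mid-pass, freezing a spur onto an otherwise
clean curve (endings are protected).  The ordering is deterministic, so
results are reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import ndimage

from skelpore.volumes import VoxelVolume, boundary

__all__ = [
    "Skeleton",
    "DistanceMap",
    "distance_transform",
    "euler_characteristic",
    "is_deletable",
    "curve_skeletonize",
]


@dataclass(frozen=True)
class Skeleton:
    """One-voxel-thick curve skeleton of a pore volume.

    ``mask`` is a boolean array over the parent volume's grid; every True
    voxel is a pore voxel of the source.  The skeleton has the same number
    of 26-components and the same Euler characteristic as the source, and
    re-thinning it changes nothing.
    """

    mask: np.ndarray
    resolution: float = 1.0

    @property
    def parent_dims(self) -> tuple[int, int, int]:
        return tuple(self.mask.shape)

    @property
    def voxels(self) -> np.ndarray:
        """(n, 3) array of skeleton voxel coordinates in lexicographic order."""
        return np.argwhere(self.mask)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def to_volume(self) -> VoxelVolume:
        return VoxelVolume(self.mask.copy(), resolution=self.resolution)


@dataclass(frozen=True)
class DistanceMap:
    """Euclidean distance of each pore voxel to the nearest background voxel
    center (voxel units); zero outside S.  Diagnostic only — thinning does
    not consume it."""

    values: np.ndarray


def distance_transform(volume: VoxelVolume) -> DistanceMap:
    """Exact Euclidean distance transform of S, border treated as background."""
    if volume.n_pore == 0:
        raise ValueError("distance transform of an empty pore set is undefined")
    padded = np.pad(volume.grid, 1)
    dist = ndimage.distance_transform_edt(padded)
    return DistanceMap(dist[1:-1, 1:-1, 1:-1])


def euler_characteristic(volume: VoxelVolume | np.ndarray) -> int:
    """Euler characteristic of the cubical complex spanned by the pore voxels.

    chi = #vertices - #edges + #faces - #octants of the union of closed unit
    cubes; for the 26-connected object this equals
    #components - #tunnels + #cavities.
    """
    g = volume.grid if isinstance(volume, VoxelVolume) else np.asarray(volume, dtype=bool)
    if g.ndim != 3:
        raise ValueError("expected a 3D boolean array")
    nx, ny, nz = g.shape
    p = np.pad(g, 1)

    # occupancy of lattice vertices: OR over the (up to) 8 incident cubes
    v = np.zeros((nx + 1, ny + 1, nz + 1), dtype=bool)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                v |= p[dx : dx + nx + 1, dy : dy + ny + 1, dz : dz + nz + 1]
    n_vertices = int(v.sum())

    n_edges = 0
    n_faces = 0
    # edges along axis a: OR over 4 incident cubes; faces normal to axis a:
    # OR over 2 incident cubes
    for axis in range(3):
        e = None
        f = None
        for d0 in (0, 1):
            for d1 in (0, 1):
                sl = [slice(1, 1 + n) for n in (nx, ny, nz)]
                off = [d0, d1]
                off.insert(axis, None)
                shape = [nx, ny, nz]
                for ax2 in range(3):
                    if ax2 == axis:
                        continue
                    o = off[ax2]
                    sl[ax2] = slice(o, o + shape[ax2] + 1)
                term = p[tuple(sl)]
                e = term if e is None else (e | term)
        n_edges += int(e.sum())
        sl = [slice(1, 1 + n) for n in (nx, ny, nz)]
        shape = [nx, ny, nz]
        for d in (0, 1):
            sl2 = list(sl)
            sl2[axis] = slice(d, d + shape[axis] + 1)
            term = p[tuple(sl2)]
            f = term if f is None else (f | term)
        n_faces += int(f.sum())

    n_octants = int(g.sum())
    return n_vertices - n_edges + n_faces - n_octants


# ---------------------------------------------------------------------------
# numba kernels: local topology tests on a 3x3x3 patch and the thinning loop
# ---------------------------------------------------------------------------


@njit(cache=False)
def _patch_chi(p):
    """Euler characteristic of the cubical complex of a 3x3x3 boolean patch."""
    n_v = 0
    for x in range(4):
        for y in range(4):
            for z in range(4):
                occ = False
                for cx in range(max(0, x - 1), min(3, x + 1)):
                    for cy in range(max(0, y - 1), min(3, y + 1)):
                        for cz in range(max(0, z - 1), min(3, z + 1)):
                            if p[cx, cy, cz]:
                                occ = True
                if occ:
                    n_v += 1
    n_e = 0
    # x-edges: x in 0..2, y,z lattice 0..3
    for x in range(3):
        for y in range(4):
            for z in range(4):
                occ = False
                for cy in range(max(0, y - 1), min(3, y + 1)):
                    for cz in range(max(0, z - 1), min(3, z + 1)):
                        if p[x, cy, cz]:
                            occ = True
                if occ:
                    n_e += 1
    # y-edges
    for y in range(3):
        for x in range(4):
            for z in range(4):
                occ = False
                for cx in range(max(0, x - 1), min(3, x + 1)):
                    for cz in range(max(0, z - 1), min(3, z + 1)):
                        if p[cx, y, cz]:
                            occ = True
                if occ:
                    n_e += 1
    # z-edges
    for z in range(3):
        for x in range(4):
            for y in range(4):
                occ = False
                for cx in range(max(0, x - 1), min(3, x + 1)):
                    for cy in range(max(0, y - 1), min(3, y + 1)):
                        if p[cx, cy, z]:
                            occ = True
                if occ:
                    n_e += 1
    n_f = 0
    # faces normal to z: x,y in 0..2, z lattice 0..3
    for x in range(3):
        for y in range(3):
            for z in range(4):
                occ = False
                for cz in range(max(0, z - 1), min(3, z + 1)):
                    if p[x, y, cz]:
                        occ = True
                if occ:
                    n_f += 1
    # faces normal to y
    for x in range(3):
        for z in range(3):
            for y in range(4):
                occ = False
                for cy in range(max(0, y - 1), min(3, y + 1)):
                    if p[x, cy, z]:
                        occ = True
                if occ:
                    n_f += 1
    # faces normal to x
    for y in range(3):
        for z in range(3):
            for x in range(4):
                occ = False
                for cx in range(max(0, x - 1), min(3, x + 1)):
                    if p[cx, y, z]:
                        occ = True
                if occ:
                    n_f += 1
    n_o = 0
    for x in range(3):
        for y in range(3):
            for z in range(3):
                if p[x, y, z]:
                    n_o += 1
    return n_v - n_e + n_f - n_o


@njit(cache=False)
def _patch_ncomp(p):
    """Number of 26-connected components of a 3x3x3 boolean patch."""
    labels = np.zeros((3, 3, 3), dtype=np.int8)
    stack = np.empty((27, 3), dtype=np.int8)
    ncomp = 0
    for sx in range(3):
        for sy in range(3):
            for sz in range(3):
                if p[sx, sy, sz] and labels[sx, sy, sz] == 0:
                    ncomp += 1
                    top = 0
                    stack[0, 0] = sx
                    stack[0, 1] = sy
                    stack[0, 2] = sz
                    labels[sx, sy, sz] = ncomp
                    top = 1
                    while top > 0:
                        top -= 1
                        x = stack[top, 0]
                        y = stack[top, 1]
                        z = stack[top, 2]
                        for nx2 in range(max(0, x - 1), min(3, x + 2)):
                            for ny2 in range(max(0, y - 1), min(3, y + 2)):
                                for nz2 in range(max(0, z - 1), min(3, z + 2)):
                                    if p[nx2, ny2, nz2] and labels[nx2, ny2, nz2] == 0:
                                        labels[nx2, ny2, nz2] = ncomp
                                        stack[top, 0] = nx2
                                        stack[top, 1] = ny2
                                        stack[top, 2] = nz2
                                        top += 1
    return ncomp


@njit(cache=False)
def _patch_deletable(p):
    """Deletion test for the center voxel of a 3x3x3 patch (conditions i-iv).

    The patch must already encode out-of-volume neighbors as background.
    """
    if not p[1, 1, 1]:
        return False
    n = 0
    for x in range(3):
        for y in range(3):
            for z in range(3):
                if p[x, y, z]:
                    n += 1
    n -= 1  # exclude the center itself
    if n >= 26:  # interior voxel, not on B: condition (i)
        return False
    if n <= 1:  # ending point or isolated voxel: condition (ii)
        return False
    chi0 = _patch_chi(p)
    c0 = _patch_ncomp(p)
    p[1, 1, 1] = False
    chi1 = _patch_chi(p)
    c1 = _patch_ncomp(p)
    p[1, 1, 1] = True
    return chi0 == chi1 and c0 == c1


@njit(cache=False)
def _delete_pass(vol, ci, cj, ck):
    """Attempt deletion of the given candidate voxels in order, re-testing
    against the already updated volume; returns the number deleted."""
    patch = np.empty((3, 3, 3), dtype=np.bool_)
    ndeleted = 0
    for t in range(len(ci)):
        i = ci[t]
        j = cj[t]
        k = ck[t]
        for a in range(3):
            for b in range(3):
                for c in range(3):
                    patch[a, b, c] = vol[i - 1 + a, j - 1 + b, k - 1 + c]
        if _patch_deletable(patch):
            vol[i, j, k] = False
            ndeleted += 1
    return ndeleted


def is_deletable(volume: VoxelVolume, voxel: tuple[int, int, int]) -> bool:
    """Whether thinning may delete ``voxel`` from the volume right now.

    Applies the four deletion conditions (boundary membership, not an ending
    point, Euler characteristic preserved, 26-component count preserved),
    the topological pair being tested on the 3x3x3 neighborhood.
    """
    i, j, k = voxel
    if not volume.grid[i, j, k]:
        raise ValueError(f"voxel {voxel} is not a pore voxel")
    padded = np.pad(volume.grid, 1)
    patch = np.ascontiguousarray(padded[i : i + 3, j : j + 3, k : k + 3])
    return bool(_patch_deletable(patch))


def curve_skeletonize(volume: VoxelVolume) -> Skeleton:
    """Thin the pore set to its curve skeleton (fixed point of deletion passes).

    Works on disconnected pore sets; single-voxel components survive (they
    are never deletable).  The result keeps the component count and Euler
    characteristic of the input and is idempotent under re-thinning.
    """
    padded = np.pad(volume.grid, 1)
    # static distance-to-boundary used only to order candidate visits
    depth = ndimage.distance_transform_edt(padded) if padded.any() else None
    conn = np.ones((3, 3, 3), dtype=np.int8)
    while padded.any():
        interior = ndimage.binary_erosion(padded, structure=conn, border_value=0)
        coords = np.argwhere(padded & ~interior)  # lexicographic
        # within a distance shell, visit the most exposed voxels (fewest
        # remaining pore neighbors) first, ties lexicographic
        n_nb = ndimage.convolve(padded.astype(np.int8), conn, mode="constant")
        keys = np.stack(
            [
                n_nb[coords[:, 0], coords[:, 1], coords[:, 2]].astype(float),
                depth[coords[:, 0], coords[:, 1], coords[:, 2]],
            ]
        )
        order = np.lexsort(keys)
        coords = coords[order]
        if _delete_pass(padded, coords[:, 0], coords[:, 1], coords[:, 2]) == 0:
            break
    return Skeleton(padded[1:-1, 1:-1, 1:-1], resolution=volume.resolution)
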