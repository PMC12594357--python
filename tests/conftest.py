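"""Shared fixtures: synthetic volumes, pipeline products and graph builders."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

import skelpore as sp
from skelpore import synthetic as syn
from skelpore.branches import BranchSet
from skelpore.poregraph import PoreGraph

CONN6 = ndimage.generate_binary_structure(3, 1)
N18 = np.ones((3, 3, 3), dtype=bool)
for _c in [(0, 0, 0), (0, 0, 2), (0, 2, 0), (0, 2, 2), (2, 0, 0), (2, 0, 2), (2, 2, 0), (2, 2, 2)]:
    N18[_c] = False


def simple_point_oracle(grid: np.ndarray, i: int, j: int, k: int) -> bool:
    """Independent simple-point test: T26 = 1 object components in the
    26-neighborhood and T6 = 1 background components in the 18-neighborhood
    6-adjacent to the center, plus the boundary/ending guards."""
    pad = np.pad(grid, 1)
    patch = pad[i : i + 3, j : j + 3, k : k + 3].copy()
    nb = patch.sum() - 1
    if nb >= 26 or nb <= 1:
        return False
    p2 = patch.copy()
    p2[1, 1, 1] = False
    lab, n26 = ndimage.label(p2, structure=np.ones((3, 3, 3)))
    if n26 != 1:
        return False
    bg_in = (~patch) & N18
    lab6, _ = ndimage.label(bg_in, structure=CONN6)
    touch = {
        lab6[d]
        for d in [(0, 1, 1), (2, 1, 1), (1, 0, 1), (1, 2, 1), (1, 1, 0), (1, 1, 2)]
        if lab6[d] > 0
    }
    return len(touch) == 1


def fixture_graph(n: int = 100, seed: int = 7) -> PoreGraph:
    """Random connected pore graph: a chain plus n/2 chords, lognormal-ish
    volumes; deterministic per seed."""
    rng = np.random.default_rng(seed)
    volumes = rng.uniform(50, 500, n)
    centroids = rng.uniform(0, 50, (n, 3))
    arcs = [[i, i + 1] for i in range(1, n)]
    extra = set()
    while len(extra) < n // 2:
        a, b = sorted(rng.integers(1, n + 1, 2))
        if a != b and b - a > 1 and (a, b) not in extra:
            extra.add((a, b))
    arcs += sorted(extra)
    arcs = np.asarray(arcs)
    faces = rng.integers(5, 40, len(arcs))
    distances = rng.uniform(3, 10, len(arcs))
    return PoreGraph(
        volumes=volumes, centroids=centroids, arcs=arcs, faces=faces, distances=distances
    )


def segmented_tube(radius: int = 4, length: int = 64, segment: int = 8):
    """Straight tube flush with the k ends, with its axis pre-segmented into
    equal branches, giving a chain of slab regions (a geometry where the
    region model of diffusion is exact)."""
    vol = syn.make_tube(radius, length, axis=2, pad=2, cap=0)
    nx, ny, _ = vol.dims
    labels = np.zeros(vol.dims, dtype=np.int32)
    for k in range(length):
        labels[nx // 2, ny // 2, k] = k // segment + 1
    branches = {b: np.argwhere(labels == b) for b in range(1, length // segment + 1)}
    bs = BranchSet(labels=labels, branches=branches)
    part = sp.assign_regions(vol, bs)
    graph = sp.build_graph(part)
    return vol, part, graph


@pytest.fixture(scope="session")
def tube_volume():
    return syn.make_tube(3, 30)


@pytest.fixture(scope="session")
def torus_volume():
    return syn.make_torus(8, 2)


@pytest.fixture(scope="session")
def y_volume():
    return syn.make_y_junction(2, 12)


@pytest.fixture(scope="session")
def cavity_volume():
    return syn.make_cavity_cube()


@pytest.fixture(scope="session")
def porous_volume():
    return syn.make_random_porous((32, 32, 32), 0.35, 2.0, seed=5)


@pytest.fixture(scope="session")
def fixture_volumes(tube_volume, torus_volume, y_volume, cavity_volume, porous_volume):
    return {
        "tube": tube_volume,
        "torus": torus_volume,
        "y_junction": y_volume,
        "cavity_cube": cavity_volume,
        "random_porous": porous_volume,
    }


@pytest.fixture(scope="session")
def fixture_partitions(fixture_volumes):
    """Full geometric pipeline on every fixture volume."""
    out = {}
    for name, vol in fixture_volumes.items():
        skel = sp.curve_skeletonize(vol)
        branches = sp.segment_branches(skel)
        out[name] = (vol, skel, branches, sp.assign_regions(vol, branches))
    return out


@pytest.fixture(scope="session")
def porous_graph_large():
    """~1600-region pore graph from a dense 64^3 random porous medium; large
    enough to place 1000 distinct biomass spots."""
    vol = syn.make_random_porous((64, 64, 64), 0.45, 1.5, seed=3)
    skel = sp.curve_skeletonize(vol)
    part = sp.assign_regions(vol, sp.segment_branches(skel))
    return vol, part, sp.build_graph(part)
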