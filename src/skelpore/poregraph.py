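"""Attributed relational graph of pore regions.

Nodes carry the region geometry (inertia center, volume in voxels); arcs
link regions that share at least one voxel face (6-adjacency) and carry the
contact-surface area as an exact integer face count plus the Euclidean
distance between the two inertia centers.  Arcs are found with a single
scan of the label image: for each pore voxel only the three
positive-direction neighbors are inspected, so every 6-adjacent voxel pair
is counted exactly once.

Contact areas stay integer face counts internally; physical square
micrometres appear only on export.  Center-to-center distances are floored
at one voxel (interlocking regions can bring centroids arbitrarily close,
and the diffusion exchange volume divides by this distance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from skelpore.partition import RegionPartition

__all__ = ["PoreGraph", "build_graph", "gci"]

log = logging.getLogger(__name__)

#: minimum admissible center-to-center distance (voxel units)
DISTANCE_FLOOR = 1.0


@dataclass(frozen=True)
class PoreGraph:
    """Pore network as plain arrays (region ids are 1-based and contiguous).

    ``arcs`` is an (M, 2) int array with ``arcs[:, 0] < arcs[:, 1]``;
    ``faces`` the per-arc contact areas in voxel faces; ``distances`` the
    per-arc centroid distances in voxel units.
    """

    volumes: np.ndarray  # (R,) voxel counts
    centroids: np.ndarray  # (R, 3) voxel units
    arcs: np.ndarray  # (M, 2) region ids
    faces: np.ndarray  # (M,) int face counts
    distances: np.ndarray  # (M,) voxel units
    resolution: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "volumes", np.asarray(self.volumes, dtype=float))
        object.__setattr__(self, "centroids", np.asarray(self.centroids, dtype=float))
        arcs = np.asarray(self.arcs, dtype=np.int64).reshape(-1, 2)
        object.__setattr__(self, "arcs", arcs)
        object.__setattr__(self, "faces", np.asarray(self.faces, dtype=np.int64).reshape(-1))
        object.__setattr__(self, "distances", np.asarray(self.distances, dtype=float).reshape(-1))
        if arcs.size and (arcs[:, 0] == arcs[:, 1]).any():
            raise ValueError("self-arcs are not allowed")

    @property
    def n_nodes(self) -> int:
        return len(self.volumes)

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)

    @property
    def node_ids(self) -> np.ndarray:
        return np.arange(1, self.n_nodes + 1)

    @property
    def total_volume(self) -> float:
        return float(self.volumes.sum())

    def to_networkx(self):
        """Export as a networkx.Graph with physical attributes."""
        import networkx as nx

        g = nx.Graph()
        res = self.resolution
        for i in range(self.n_nodes):
            g.add_node(
                i + 1,
                volume_voxels=float(self.volumes[i]),
                volume_um3=float(self.volumes[i]) * res**3,
                centroid_i=float(self.centroids[i, 0]),
                centroid_j=float(self.centroids[i, 1]),
                centroid_k=float(self.centroids[i, 2]),
            )
        for (a, b), s, d in zip(self.arcs, self.faces, self.distances):
            g.add_edge(
                int(a),
                int(b),
                faces=int(s),
                area_um2=float(s) * res**2,
                distance_voxels=float(d),
                distance_um=float(d) * res,
            )
        return g

    def write_graphml(self, path: str | Path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), str(path))

    def edge_table(self) -> pd.DataFrame:
        res = self.resolution
        return pd.DataFrame(
            {
                "region_a": self.arcs[:, 0],
                "region_b": self.arcs[:, 1],
                "faces": self.faces,
                "area_um2": self.faces * res**2,
                "distance_voxels": self.distances,
                "distance_um": self.distances * res,
            }
        )


def build_graph(partition: RegionPartition, resolution: float | None = None) -> PoreGraph:
    """One-pass scan of the label image into a PoreGraph.

    For each pore voxel the three neighbors (i+1, j, k), (i, j+1, k) and
    (i, j, k+1) are compared; differing nonzero labels create or increment
    an arc.  Edge/corner contacts do not create arcs (a contact *area*
    requires shared faces).
    """
    labels = partition.labels
    res = partition.resolution if resolution is None else resolution
    pairs = []
    for axis in range(3):
        a = [slice(None)] * 3
        b = [slice(None)] * 3
        a[axis] = slice(None, -1)
        b[axis] = slice(1, None)
        la = labels[tuple(a)].ravel()
        lb = labels[tuple(b)].ravel()
        m = (la > 0) & (lb > 0) & (la != lb)
        if m.any():
            p = np.stack([la[m], lb[m]], axis=1)
            pairs.append(np.sort(p, axis=1))
    if pairs:
        allp = np.concatenate(pairs, axis=0)
        arcs, faces = np.unique(allp, axis=0, return_counts=True)
    else:
        arcs = np.empty((0, 2), dtype=np.int64)
        faces = np.empty((0,), dtype=np.int64)

    centroids = partition.centroids
    volumes = partition.volumes
    if len(arcs):
        delta = centroids[arcs[:, 0] - 1] - centroids[arcs[:, 1] - 1]
        distances = np.sqrt((delta**2).sum(axis=1))
        floored = distances < DISTANCE_FLOOR
        if floored.any():
            log.info("floored %d arc distances at %.1f voxel", int(floored.sum()), DISTANCE_FLOOR)
            distances = np.maximum(distances, DISTANCE_FLOOR)
    else:
        distances = np.empty((0,), dtype=float)
    return PoreGraph(
        volumes=volumes,
        centroids=centroids,
        arcs=arcs,
        faces=faces,
        distances=distances,
        resolution=res,
    )


def gci(graph: PoreGraph) -> float:
    """Global Connectivity Indicator: number of arcs / number of nodes."""
    if graph.n_nodes == 0:
        raise ValueError("GCI is undefined for an empty graph")
    return graph.n_arcs / graph.n_nodes


def make_graph_with_counts(n_nodes: int, n_arcs: int) -> PoreGraph:
    """Construct a valid PoreGraph with prescribed node and arc tallies.

    Used for connectivity-indicator arithmetic on networks whose node/arc
    counts are known (e.g. published network summaries) without their full
    geometry: nodes get unit volumes, arcs connect node i to node i+j
    (cyclically) for increasing strides j, which keeps all pairs distinct
    while n_arcs <= n_nodes * (n_nodes - 1) / 2.
    """
    if n_nodes < 1:
        raise ValueError("need at least one node")
    max_arcs = n_nodes * (n_nodes - 1) // 2
    if n_arcs > max_arcs:
        raise ValueError(f"{n_arcs} arcs impossible with {n_nodes} nodes")
    ids = np.arange(1, n_nodes + 1, dtype=np.int64)
    pairs = []
    remaining = n_arcs
    # strides 1 .. n//2 enumerate every unordered pair exactly once
    for stride in range(1, n_nodes // 2 + 1):
        if remaining <= 0:
            break
        a = ids if 2 * stride != n_nodes else ids[: n_nodes // 2]
        b = (a - 1 + stride) % n_nodes + 1
        pair = np.sort(np.stack([a, b], axis=1), axis=1)[:remaining]
        pairs.append(pair)
        remaining -= len(pair)
    arcs = np.concatenate(pairs, axis=0) if pairs else np.empty((0, 2), dtype=np.int64)
    return PoreGraph(
        volumes=np.ones(n_nodes),
        centroids=np.zeros((n_nodes, 3)),
        arcs=arcs,
        faces=np.ones(len(arcs), dtype=np.int64),
        distances=np.ones(len(arcs)),
    )
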