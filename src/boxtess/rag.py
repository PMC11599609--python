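"""Region-adjacency graph from a labeled scute segmentation.

One node per scute, placed at the scute's voxel centroid in world (mm)
coordinates; one edge per pair of scutes whose voxels share at least
``min_contact`` face-adjacent voxel pairs (6-connectivity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy import ndimage


@dataclass
class LabelVolume:
    """3D integer label field (0 = background) with voxel spacing in mm.

    World coordinates of voxel (i, j, k) are ``origin + (index + 0.5) *
    spacing``.
    """

    labels: np.ndarray
    voxel_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if np.any(self.labels < 0):
            raise ValueError("labels must be non-negative")
        if any(s <= 0 for s in self.voxel_mm):
            raise ValueError("voxel spacing must be positive")

    @property
    def scute_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_mm))

    def world_coords(self, index_array: np.ndarray) -> np.ndarray:
        """Map integer voxel indices (n, 3) to world mm coordinates."""
        return (np.asarray(index_array) + 0.5) * np.asarray(self.voxel_mm) \
            + np.asarray(self.origin_mm)


@dataclass
class AdjacencyGraph:
    """Scute centers plus neighbor edges (the RAG)."""

    nodes: dict[int, np.ndarray]
    edges: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self):
        for a, b in self.edges:
            if a == b:
                raise ValueError("self-edges are not allowed")
        self.edges = {(min(a, b), max(a, b)) for a, b in self.edges}

    def degree(self, scute_id: int) -> int:
        if scute_id not in self.nodes:
            raise KeyError(f"scute {scute_id} not in graph")
        return sum(scute_id in e for e in self.edges)

    def neighbors(self, scute_id: int) -> set[int]:
        if scute_id not in self.nodes:
            raise KeyError(f"scute {scute_id} not in graph")
        return {b if a == scute_id else a
                for a, b in self.edges if scute_id in (a, b)}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for sid, c in self.nodes.items():
            g.add_node(sid, center=np.asarray(c))
        g.add_edges_from(self.edges)
        return g


def build_rag(volume: LabelVolume, min_contact: int = 1,
              prune_nongeneric: bool = False) -> AdjacencyGraph:
    """RAG of a label volume under 6-connectivity face contacts.

    An edge joins two scutes iff at least ``min_contact`` pairs of their
    voxels share a face; corner or edge (diagonal) contacts never count.

    With ``prune_nongeneric`` the graph is additionally reduced to a
    generic surface tessellation: in every 4-clique (four mutually
    touching scutes — impossible at a generic junction of a trivalent
    tiling, and in practice a voxel-quantization artifact where two
    scutes meet diagonally across a near-4-way junction) the contact
    with the fewest shared voxel faces is removed, until no 4-clique
    remains.
    """
    lab = volume.labels
    ids = volume.scute_ids
    if len(ids) == 0:
        raise ValueError("label volume contains no scutes")

    pair_counts: dict[tuple[int, int], int] = {}
    for axis in range(3):
        a = np.moveaxis(lab, axis, 0)[:-1].ravel()
        b = np.moveaxis(lab, axis, 0)[1:].ravel()
        sel = (a != b) & (a > 0) & (b > 0)
        if not np.any(sel):
            continue
        lo = np.minimum(a[sel], b[sel]).astype(np.int64)
        hi = np.maximum(a[sel], b[sel]).astype(np.int64)
        key = lo * (lab.max() + 1) + hi
        uniq, counts = np.unique(key, return_counts=True)
        for k, c in zip(uniq, counts):
            pair = (int(k // (lab.max() + 1)), int(k % (lab.max() + 1)))
            pair_counts[pair] = pair_counts.get(pair, 0) + int(c)

    edges = {p for p, c in pair_counts.items() if c >= min_contact}

    centers = ndimage.center_of_mass(np.ones_like(lab, dtype=np.uint8),
                                     labels=lab, index=ids)
    nodes = {int(sid): volume.world_coords(np.asarray(c))
             for sid, c in zip(ids, centers)}
    if prune_nongeneric:
        edges = _prune_k4(edges, pair_counts, nodes)
    return AdjacencyGraph(nodes=nodes, edges=edges)


def _prune_k4(edges: set, pair_counts: dict, nodes: dict) -> set:
    """Drop one quad diagonal from every 4-clique until none remain.

    In each 4-clique the two center-to-center longest contacts are the
    candidate quad diagonals; the one with fewer shared voxel faces is
    the quantization artifact and is removed.
    """
    edges = set(edges)

    def length(e):
        return float(np.linalg.norm(nodes[e[0]] - nodes[e[1]]))

    while True:
        nbrs: dict[int, set[int]] = {}
        for a, b in edges:
            nbrs.setdefault(a, set()).add(b)
            nbrs.setdefault(b, set()).add(a)
        victims = set()
        for a, b in sorted(edges):
            common = sorted(nbrs[a] & nbrs[b])
            for i, c in enumerate(common):
                for d in common[i + 1:]:
                    if d in nbrs[c]:  # K4 on {a, b, c, d}
                        k4 = [(min(u, v), max(u, v))
                              for u, v in [(a, b), (a, c), (a, d),
                                           (b, c), (b, d), (c, d)]]
                        diags = sorted(k4, key=length)[-2:]
                        victims.add(min(diags,
                                        key=lambda e: (pair_counts[e], e)))
        if not victims:
            return edges
        edges -= victims


def count_neighbors(graph: AdjacencyGraph, scute_id: int) -> int:
    """Degree of a scute in the RAG (6 neighbors = hexagonal scute)."""
    return graph.degree(scute_id)
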