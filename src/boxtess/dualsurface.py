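"""Carapace surface reconstruction from the region-adjacency graph.

The RAG's mutually adjacent scute triples (plus genuine quads at
four-sided junctions) form an initial surface complex with scute centers
as vertices.  Its dual — one vertex per triangle/quad, one polygon
around every fully surrounded scute — approximates the carapace surface
and yields a surface patch per scute.  The dual is midpoint-subdivided
three times and Laplacian-smoothed (10 iterations, relaxation 0.7),
after which the carapace surface area and the per-scute plane-based
areas are measured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import sparse

from .rag import AdjacencyGraph


@dataclass
class CarapaceSurface:
    """Smoothed dual surface with per-scute face patches.

    ``scute_patch`` maps scute id → face indices of its dual polygon
    (after refinement); scutes whose RAG vertex is not completely
    surrounded by triangles (e.g. bordering a carapace opening) have no
    patch.
    """

    mesh: trimesh.Trimesh
    scute_patch: dict[int, np.ndarray] = field(default_factory=dict)


def triangulate_rag(graph: AdjacencyGraph) -> tuple[np.ndarray, np.ndarray,
                                                    list[int]]:
    """Vertices (scute centers), triangle array, and vertex-id order.

    A triangle connects every mutually adjacent scute triple.  Quads
    (see :func:`rag_faces`) are not included here.
    """
    verts, faces, ids = rag_faces(graph)
    tris = np.array(sorted(f for f in faces if len(f) == 3))
    return verts, tris, ids


def rag_faces(graph: AdjacencyGraph):
    """Faces of the RAG's surface complex: triangles plus genuine quads.

    Triangles are the mutually adjacent scute triples.  A chordless
    4-cycle (four scutes adjacent in a cycle, neither diagonal present)
    is kept as a quad face when its cycle edges are not already
    saturated by two triangles each — at such junctions the tessellation
    locally has four-sided tiles and dropping the quad would punch a
    hole into the dual surface.
    """
    from itertools import combinations

    ids = sorted(graph.nodes)
    index = {sid: i for i, sid in enumerate(ids)}
    verts = np.array([graph.nodes[sid] for sid in ids], dtype=float)
    nbrs = {sid: set() for sid in ids}
    for a, b in graph.edges:
        nbrs[a].add(b)
        nbrs[b].add(a)

    faces: list[tuple] = []
    edge_load: dict[tuple, int] = {}
    for a in ids:
        for b in nbrs[a]:
            if b <= a:
                continue
            for c in nbrs[a] & nbrs[b]:
                if c > b:
                    faces.append((index[a], index[b], index[c]))
                    for e in ((a, b), (a, c), (b, c)):
                        e = (min(e), max(e))
                        edge_load[e] = edge_load.get(e, 0) + 1

    seen = set()
    for u in ids:
        for v, x in combinations(sorted(nbrs[u]), 2):
            if x in nbrs[v]:
                continue
            for w in sorted((nbrs[v] & nbrs[x]) - {u}):
                if w in nbrs[u]:
                    continue
                key = frozenset((u, v, w, x))
                if key in seen:
                    continue
                seen.add(key)
                cycle = [(u, v), (v, w), (w, x), (x, u)]
                if all(edge_load.get((min(e), max(e)), 0) < 2
                       for e in cycle):
                    faces.append((index[u], index[v], index[w], index[x]))
                    for e in cycle:
                        e = (min(e), max(e))
                        edge_load[e] = edge_load.get(e, 0) + 1

    if not any(len(f) == 3 for f in faces):
        raise ValueError("RAG contains no mutually adjacent scute triples")
    return verts, faces, ids


def _orient_outward(mesh: trimesh.Trimesh) -> None:
    """Consistent winding, then flip so normals point away from center."""
    trimesh.repair.fix_normals(mesh)
    center = mesh.vertices.mean(axis=0)
    out = mesh.triangles_center - center
    score = np.einsum("ij,ij->i", mesh.face_normals, out)
    if np.sum(score > 0) < np.sum(score < 0):
        mesh.invert()


def build_dual_surface(graph: AdjacencyGraph, n_refine: int = 3,
                       smooth_iterations: int = 10,
                       smooth_lambda: float = 0.7) -> CarapaceSurface:
    """Dual surface of the RAG triangulation, refined and smoothed.

    Steps: triangulate the RAG; fix orientation; place one dual vertex
    per triangle and build the polygon of triangles around each fully
    surrounded scute; fix orientation again; midpoint-subdivide
    ``n_refine`` times; umbrella Laplacian smoothing.
    """
    verts, faces, ids = rag_faces(graph)

    # dual vertices: one per primal face (triangle or quad), at its
    # centroid
    dual_verts = np.array([verts[list(f)].mean(axis=0) for f in faces])

    # ring of faces around each primal vertex, ordered by shared edges
    incident: dict[int, list[int]] = {i: [] for i in range(len(verts))}
    for t, f in enumerate(faces):
        for v in f:
            incident[v].append(t)

    dual_faces: list[tuple[int, int, int]] = []
    scute_patch: dict[int, list[int]] = {}
    for vi, face_list in incident.items():
        ring = _ordered_ring(vi, face_list, faces)
        if ring is None:
            continue  # not fully surrounded: no patch for this scute
        # fan-triangulate the dual polygon
        start = len(dual_faces)
        for k in range(1, len(ring) - 1):
            dual_faces.append((ring[0], ring[k], ring[k + 1]))
        scute_patch[ids[vi]] = list(range(start, len(dual_faces)))

    if not dual_faces:
        raise ValueError("dual surface is empty")
    dual_faces = np.array(dual_faces)
    # drop dual vertices not used by any closed ring
    used = np.unique(dual_faces)
    remap = np.full(len(dual_verts), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    mesh = trimesh.Trimesh(vertices=dual_verts[used],
                           faces=remap[dual_faces], process=False)
    _orient_outward(mesh)

    face_owner = np.full(len(mesh.faces), -1, dtype=np.int64)
    for sid, fl in scute_patch.items():
        face_owner[fl] = sid

    v, f = mesh.vertices.view(np.ndarray), mesh.faces.view(np.ndarray)
    for _ in range(n_refine):
        v, f, face_owner = _midpoint_subdivide(v, f, face_owner)
    v = _laplacian_smooth(v, f, smooth_iterations, smooth_lambda)

    out = trimesh.Trimesh(vertices=v, faces=f, process=False)
    patches = {int(sid): np.flatnonzero(face_owner == sid)
               for sid in scute_patch}
    return CarapaceSurface(mesh=out, scute_patch=patches)


def _ordered_ring(vi, face_list, faces):
    """Order the faces around vertex ``vi`` into a closed cycle.

    Each incident face (triangle or cycle-ordered quad) contributes the
    two cycle-neighbors of ``vi`` as ring connectors.  Returns None when
    the ring is open (border scute) or irregular: a closed ring requires
    every connector vertex to appear in exactly two incident faces.
    """
    if len(face_list) < 3:
        return None
    others = {}
    by_vertex: dict[int, list[int]] = {}
    for t in face_list:
        f = faces[t]
        pos = f.index(vi)
        n = len(f)
        pair = [f[(pos - 1) % n], f[(pos + 1) % n]]
        others[t] = pair
        for x in pair:
            by_vertex.setdefault(x, []).append(t)
    if any(len(ts) != 2 for ts in by_vertex.values()):
        return None
    start = face_list[0]
    ring = [start]
    current, via = start, others[start][1]
    while True:
        t1, t2 = by_vertex[via]
        nxt = t2 if t1 == current else t1
        if nxt == start:
            return ring if len(ring) == len(face_list) else None
        ring.append(nxt)
        if len(ring) > len(face_list):
            return None
        a, b = others[nxt]
        current, via = nxt, (b if a == via else a)


def _midpoint_subdivide(v, f, face_owner):
    """1-to-4 midpoint subdivision; children inherit the face owner."""
    edges = np.sort(np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]),
                    axis=1)
    uniq, inv = np.unique(edges, axis=0, return_inverse=True)
    mid = 0.5 * (v[uniq[:, 0]] + v[uniq[:, 1]])
    mids = len(v) + inv.reshape(3, -1)  # per-face midpoint vertex ids
    m01, m12, m20 = mids[0], mids[1], mids[2]
    a, b, c = f[:, 0], f[:, 1], f[:, 2]
    nf = np.concatenate([
        np.column_stack([a, m01, m20]),
        np.column_stack([m01, b, m12]),
        np.column_stack([m20, m12, c]),
        np.column_stack([m01, m12, m20]),
    ])
    owner = np.concatenate([face_owner] * 4)
    # regroup children so each original face's 4 children are contiguous
    order = np.argsort(np.tile(np.arange(len(f)), 4), kind="stable")
    return np.vstack([v, mid]), nf[order], owner[order]


def _laplacian_smooth(v, f, iterations, lamb):
    """Umbrella-operator smoothing: v += lamb * (mean(neighbors) - v)."""
    edges = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    n = len(v)
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    adj = sparse.coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n)).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1
    out = v.astype(float).copy()
    for _ in range(iterations):
        out += lamb * (adj.dot(out) / deg[:, None] - out)
    return out


def surface_area(surface: CarapaceSurface) -> float:
    """Total area (mm²): the body-size variable SA of all regressions."""
    areas = surface.mesh.area_faces
    if np.any(areas <= 0):
        warnings.warn("degenerate triangles contribute zero area",
                      stacklevel=2)
    if len(areas) == 0:
        raise ValueError("empty surface mesh")
    return float(areas.sum())
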