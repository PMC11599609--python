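"""File formats: label volumes (TIFF), per-scute tables (CSV), meshes (PLY).

Label volumes are multi-page TIFF stacks with voxel spacing and origin
stored as JSON in the ImageDescription tag; per-scute tables follow the
supplementary-data schema (one row per scute, columns ``specimen,
scute_id, x, y, z, n_neighbors, volume, area, thickness, width,
aspect_ratio, cgs, cms``) with an optional column-mapping to adapt
foreign headers; meshes are ASCII PLY, optionally carrying one scalar
property per face (scute label or a color-coded variable).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import trimesh

from .morphometrics import S1_COLUMNS
from .rag import LabelVolume


# ---------------------------------------------------------------------------
# label volumes

def write_label_volume(path, volume: LabelVolume) -> None:
    meta = {"voxel_mm": list(volume.voxel_mm),
            "origin_mm": list(volume.origin_mm)}
    tifffile.imwrite(path, volume.labels.astype(np.int32),
                     description=json.dumps(meta))


def read_label_volume(path) -> LabelVolume:
    with tifffile.TiffFile(path) as tif:
        labels = tif.asarray()
        desc = tif.pages[0].tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (json.JSONDecodeError, TypeError):
                meta = {}
    voxel = tuple(meta.get("voxel_mm", (1.0, 1.0, 1.0)))
    origin = tuple(meta.get("origin_mm", (0.0, 0.0, 0.0)))
    return LabelVolume(labels=np.asarray(labels), voxel_mm=voxel,
                       origin_mm=origin)


# ---------------------------------------------------------------------------
# per-scute tables

def write_scute_table(path, records: pd.DataFrame) -> None:
    records.to_csv(path, index=False)


def read_scute_table(path, column_mapping: dict | None = None
                     ) -> pd.DataFrame:
    """Read a per-scute CSV, renaming foreign headers via the mapping.

    ``column_mapping`` maps schema names to the file's actual headers,
    e.g. ``{"cgs": "Gaussian curvature"}``.
    """
    df = pd.read_csv(path)
    if column_mapping:
        inverse = {v: k for k, v in column_mapping.items()}
        df = df.rename(columns=inverse)
    missing = [c for c in S1_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"scute table lacks columns {missing}")
    return df[S1_COLUMNS + [c for c in df.columns if c not in S1_COLUMNS]]


# ---------------------------------------------------------------------------
# meshes with a per-face scalar property

def write_ply(path, mesh: trimesh.Trimesh,
              face_scalar: np.ndarray | None = None,
              scalar_name: str = "label") -> None:
    """ASCII PLY with an optional float scalar per face."""
    v = mesh.vertices
    f = mesh.faces
    lines = ["ply", "format ascii 1.0",
             f"element vertex {len(v)}",
             "property float x", "property float y", "property float z",
             f"element face {len(f)}",
             "property list uchar int vertex_indices"]
    if face_scalar is not None:
        face_scalar = np.asarray(face_scalar, dtype=float)
        if len(face_scalar) != len(f):
            raise ValueError("face_scalar must have one value per face")
        lines.append(f"property float {scalar_name}")
    lines.append("end_header")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(fh, v, fmt="%.9g")
        if face_scalar is None:
            for tri in f:
                fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
        else:
            for tri, s in zip(f, face_scalar):
                fh.write(f"3 {tri[0]} {tri[1]} {tri[2]} {s:.17g}\n")


def read_ply(path):
    """Read an ASCII PLY written by :func:`write_ply`.

    Returns (mesh, face_scalar or None, scalar_name or None).
    """
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError("not a PLY file")
        n_v = n_f = 0
        scalar_name = None
        elem = None
        while True:
            line = fh.readline().strip()
            if line == "end_header":
                break
            parts = line.split()
            if parts[0] == "element":
                elem = parts[1]
                if elem == "vertex":
                    n_v = int(parts[2])
                else:
                    n_f = int(parts[2])
            elif (parts[0] == "property" and elem == "face"
                  and parts[1] != "list"):
                scalar_name = parts[2]
        verts = np.array([fh.readline().split() for _ in range(n_v)],
                         dtype=float)
        faces = []
        scalars = [] if scalar_name else None
        for _ in range(n_f):
            parts = fh.readline().split()
            k = int(parts[0])
            faces.append([int(x) for x in parts[1:1 + k]])
            if scalar_name:
                scalars.append(float(parts[1 + k]))
    mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces),
                           process=False)
    scal = np.array(scalars) if scalar_name else None
    return mesh, scal, scalar_name


# ---------------------------------------------------------------------------
# graphs and configs

def write_graph(nodes_path, edges_path, graph) -> None:
    rows = [{"scute_id": sid, "x": c[0], "y": c[1], "z": c[2]}
            for sid, c in sorted(graph.nodes.items())]
    pd.DataFrame(rows).to_csv(nodes_path, index=False)
    pd.DataFrame(sorted(graph.edges),
                 columns=["scute_a", "scute_b"]).to_csv(edges_path,
                                                        index=False)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
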