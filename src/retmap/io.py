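"""File formats: TSV measurement tables, FreeSurfer surfaces and morph
files (via nibabel), OFF meshes, and JSON reports with provenance headers.

All angles in files are degrees.  TSV tables are keyed by ``vertex_id``;
row order never matters.  Writers emit a provenance comment block (tool
version, config hash, seed) which readers tolerate and preserve.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import InferredMaps, RetinotopyData
from .mesh import FlatMap, Mesh3D

__all__ = [
    "read_prf_table",
    "write_prf_table",
    "write_inferred_table",
    "read_freesurfer_surface",
    "write_freesurfer_surface",
    "read_freesurfer_morph",
    "write_freesurfer_morph",
    "read_off",
    "write_off",
    "config_hash",
    "provenance_header",
]

PRF_COLUMNS = ("vertex_id", "polar_angle_deg", "eccentricity_deg",
               "prf_size_deg", "variance_explained")


class FormatError(ValueError):
    pass


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    text = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def provenance_header(config=None, seed=None) -> str:
    from . import __version__
    lines = [f"# retmap {__version__}"]
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    return "\n".join(lines) + "\n"


# ------------------------------------------------------------------ TSV

def read_prf_table(path) -> RetinotopyData:
    """Read a per-vertex pRF measurement table.

    Required columns: vertex_id, polar_angle_deg, eccentricity_deg,
    prf_size_deg, variance_explained.  Unknown columns are preserved on
    the returned object (``extra`` attribute); rows may appear in any
    order and are sorted by vertex_id.
    """
    df = pd.read_csv(path, sep="\t", comment="#",
                     float_precision="round_trip")
    missing = [c for c in PRF_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) "
                          + ", ".join(missing))
    for col in PRF_COLUMNS:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.values)[0]) + 2  # 1-based + header
            raise FormatError(
                f"{path}: non-numeric value in column {col!r} at line {line}")
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.sort_values("vertex_id").reset_index(drop=True)
    data = RetinotopyData(
        theta=df["polar_angle_deg"].to_numpy(float),
        rho=df["eccentricity_deg"].to_numpy(float),
        size=df["prf_size_deg"].to_numpy(float),
        omega=df["variance_explained"].to_numpy(float),
        vertex_id=df["vertex_id"].to_numpy(),
    )
    data.extra = df[[c for c in df.columns if c not in PRF_COLUMNS]]
    return data


def write_prf_table(path, data: RetinotopyData, config=None,
                    seed=None) -> None:
    df = pd.DataFrame({
        "vertex_id": data.vertex_id,
        "polar_angle_deg": data.theta,
        "eccentricity_deg": data.rho,
        "prf_size_deg": data.size,
        "variance_explained": data.omega,
    })
    with open(path, "w") as fh:
        fh.write(provenance_header(config, seed))
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def write_inferred_table(path, maps: InferredMaps, config=None,
                         seed=None) -> None:
    df = pd.DataFrame({
        "vertex_id": maps.vertex_id,
        "polar_angle_deg": maps.theta,
        "eccentricity_deg": maps.rho,
        "prf_size_deg": maps.size,
        "visual_area": maps.area,
    })
    with open(path, "w") as fh:
        fh.write(provenance_header(config, seed))
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_inferred_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#",
                     float_precision="round_trip")
    need = ("vertex_id", "polar_angle_deg", "eccentricity_deg")
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) "
                          + ", ".join(missing))
    return df.sort_values("vertex_id").reset_index(drop=True)


# ------------------------------------------------------- FreeSurfer formats

def read_freesurfer_surface(path) -> Mesh3D:
    """Read a FreeSurfer binary triangle surface (big-endian, magic
    0xFFFFFE)."""
    from nibabel.freesurfer.io import read_geometry
    try:
        verts, faces = read_geometry(str(path))
    except ValueError as exc:
        raise FormatError(f"{path}: not a FreeSurfer surface ({exc})") from None
    return Mesh3D(np.asarray(verts, float), np.asarray(faces, np.intp))


def write_freesurfer_surface(path, mesh: Mesh3D) -> None:
    from nibabel.freesurfer.io import write_geometry
    write_geometry(str(path), mesh.vertices, mesh.faces)


def read_freesurfer_morph(path, n_vertices: int | None = None) -> np.ndarray:
    """Read a FreeSurfer 'curv' per-vertex scalar file."""
    from nibabel.freesurfer.io import read_morph_data
    try:
        vals = np.asarray(read_morph_data(str(path)), float)
    except ValueError as exc:
        raise FormatError(f"{path}: not a FreeSurfer morph file ({exc})") \
            from None
    if n_vertices is not None and len(vals) != n_vertices:
        raise FormatError(
            f"{path}: {len(vals)} values for a {n_vertices}-vertex mesh")
    return vals


def write_freesurfer_morph(path, values: np.ndarray) -> None:
    from nibabel.freesurfer.io import write_morph_data
    write_morph_data(str(path), np.asarray(values, dtype=">f4"))


# --------------------------------------------------------------------- OFF

def read_off(path):
    """Read an OFF mesh; returns (vertices (n,d) float, faces (m,3) int)."""
    with open(path) as fh:
        tokens = []
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                tokens.extend(line.split())
    if not tokens or tokens[0] != "OFF":
        raise FormatError(f"{path}: missing OFF header")
    try:
        nv, nf = int(tokens[1]), int(tokens[2])
        pos = 4  # skip edge count
        dim = 3
        verts = np.array(tokens[pos:pos + nv * dim], float).reshape(nv, dim)
        pos += nv * dim
        faces = []
        for _ in range(nf):
            k = int(tokens[pos])
            faces.append([int(t) for t in tokens[pos + 1:pos + 1 + k]])
            pos += 1 + k
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: truncated or malformed OFF ({exc})") \
            from None
    faces = np.array(faces, dtype=np.intp)
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise FormatError(f"{path}: only triangle faces are supported")
    return verts, faces


def write_off(path, vertices: np.ndarray, faces: np.ndarray) -> None:
    v = np.asarray(vertices, float)
    if v.shape[1] == 2:  # pad flat maps to 3D per the format
        v = np.column_stack([v, np.zeros(len(v))])
    f = np.asarray(faces, int)
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(v)} {len(f)} 0\n")
        for row in v:
            fh.write(" ".join(repr(float(c)) for c in row) + "\n")
        for row in f:
            fh.write("3 " + " ".join(str(int(c)) for c in row) + "\n")


def flatmap_from_off(path) -> FlatMap:
    verts, faces = read_off(path)
    if np.allclose(verts[:, 2], 0.0):
        return FlatMap(verts[:, :2], faces)
    raise FormatError(f"{path}: expected a flat (z = 0) mesh")
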