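"""Triangle-mesh containers and geometry primitives.

Everything downstream (model building, registration, evaluation) operates on
one of two containers defined here: :class:`Mesh3D`, a cortical surface mesh
in 3D millimetre coordinates, and :class:`FlatMap`, a 2D-projected triangle
mesh carrying the combinatorial structure (edges, corner-angle triples,
perimeter) that the registration potential is written in terms of.

Angles are radians internally; degrees appear only at file interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Mesh3D",
    "MapProjection",
    "FlatMap",
    "orthographic_project",
    "edge_lengths",
    "corner_angles",
    "triangle_field_sign",
    "vertex_surface_areas",
    "barycentric_interpolate",
    "uniform_resample",
]

#: Signed face area below which a face is treated as degenerate.
DEGENERATE_AREA = 1e-12


class MeshError(ValueError):
    """Invalid mesh input (non-spherical projection source, empty selection...)."""


def _unique_edges(faces: np.ndarray) -> np.ndarray:
    """Undirected edge set: each pair appears once, as (min, max)."""
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.sort(e, axis=1)
    return np.unique(e, axis=0)


def _angle_triples(faces: np.ndarray) -> np.ndarray:
    """Corner descriptors (a, b, c): the CCW angle at a between (a,b), (a,c).

    Three per face, in face order; for a CCW face (a,b,c) the corners are
    (a,b,c), (b,c,a), (c,a,b) so every corner angle is interior.
    """
    return np.concatenate(
        [faces, faces[:, [1, 2, 0]], faces[:, [2, 0, 1]]]
    ).reshape(3, -1, 3).transpose(1, 0, 2).reshape(-1, 3)


def _signed_areas(coords: np.ndarray, faces: np.ndarray) -> np.ndarray:
    a, b, c = coords[faces[:, 0]], coords[faces[:, 1]], coords[faces[:, 2]]
    u = b - a
    v = c - a
    return 0.5 * (u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])


def _boundary_vertices(faces: np.ndarray) -> np.ndarray:
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.sort(e, axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    return np.unique(uniq[counts == 1])


@dataclass
class Mesh3D:
    """A triangle mesh in 3D (mm), e.g. a FreeSurfer white or sphere surface."""

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray     # (m, 3) int
    fields: dict = field(default_factory=dict)  # optional per-vertex scalars

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.intp)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be an (m, 3) array")
        if self.faces.size and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise MeshError("face index out of range")
        if np.any(self.faces[:, 0] == self.faces[:, 1]) or \
           np.any(self.faces[:, 1] == self.faces[:, 2]) or \
           np.any(self.faces[:, 0] == self.faces[:, 2]):
            raise MeshError("faces must have three distinct vertices")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass
class MapProjection:
    """Orthographic projection of a spherical cortical surface to 2D.

    Parameters
    ----------
    center:
        Unit 3-vector; the point of the sphere mapped to the map origin.
        Defaults point toward the occipital pole of a sphere in RAS-like
        orientation (-y axis).
    orientation_deg:
        In-plane rotation (degrees, CCW) applied after projection.
    radius_deg:
        Angular extent retained around the center, in degrees of the
        cortical sphere; must lie in (0, 90].
    chirality:
        'lh' or 'rh'.  The left hemisphere's map is mirrored (x negated)
        so both hemispheres share one in-map orientation convention.
    """

    center: np.ndarray = field(default_factory=lambda: np.array([0.0, -1.0, 0.0]))
    orientation_deg: float = 0.0
    radius_deg: float = 90.0
    chirality: str = "rh"

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        nrm = np.linalg.norm(self.center)
        if not np.isfinite(nrm) or nrm == 0:
            raise MeshError("projection center must be a nonzero vector")
        self.center = self.center / nrm
        if not (0.0 < self.radius_deg <= 90.0):
            raise MeshError("projection radius must lie in (0, 90] degrees")
        if self.chirality not in ("lh", "rh"):
            raise MeshError("chirality must be 'lh' or 'rh'")

    def rotation(self) -> np.ndarray:
        """3x3 rotation taking ``center`` to the +z pole, then the in-plane turn."""
        c = self.center
        z = np.array([0.0, 0.0, 1.0])
        v = np.cross(c, z)
        s = np.linalg.norm(v)
        d = float(np.dot(c, z))
        if s < 1e-15:
            base = np.eye(3) if d > 0 else np.diag([1.0, -1.0, -1.0])
        else:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            base = np.eye(3) + vx + vx @ vx * ((1 - d) / s**2)
        t = np.deg2rad(self.orientation_deg)
        rz = np.array([[np.cos(t), -np.sin(t), 0],
                       [np.sin(t), np.cos(t), 0],
                       [0, 0, 1.0]])
        return rz @ base


class FlatMap:
    """A 2D triangle mesh with the registration-relevant structure attached.

    Attributes
    ----------
    coordinates : (n, 2) float array
    faces : (m, 3) int array, counter-clockwise
    edges : (|E|, 2) int array, each undirected edge once as (min, max)
    angle_triples : (|Θ|, 3) int array of corner descriptors (a, b, c)
    perimeter : int array of boundary-vertex indices
    mean_edge_length : float, the ε of the registration potential
    fields : dict of per-vertex arrays
    """

    def __init__(self, coordinates, faces, fields=None, fix_orientation=True):
        coords = np.asarray(coordinates, dtype=float)
        faces = np.asarray(faces, dtype=np.intp)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise MeshError("coordinates must be an (n, 2) array")
        if faces.size == 0:
            raise MeshError("flat map has no faces")
        sa = _signed_areas(coords, faces)
        if fix_orientation:
            flip = sa < 0
            faces = faces.copy()
            faces[flip] = faces[flip][:, ::-1]
            sa = np.abs(sa)
        self.coordinates = coords
        self.faces = faces
        self.degenerate_faces = np.flatnonzero(np.abs(sa) < DEGENERATE_AREA)
        good = np.abs(sa) >= DEGENERATE_AREA
        self.edges = _unique_edges(faces)
        self.angle_triples = _angle_triples(faces[good])
        self.perimeter = _boundary_vertices(faces)
        lens = edge_lengths(coords, self.edges)
        self.mean_edge_length = float(lens.mean())
        if not self.mean_edge_length > 0:
            raise MeshError("degenerate flat map: mean edge length is 0")
        self.fields = dict(fields) if fields else {}
        self._face_tree: cKDTree | None = None

    @property
    def n_vertices(self) -> int:
        return len(self.coordinates)

    def signed_face_areas(self) -> np.ndarray:
        return _signed_areas(self.coordinates, self.faces)

    def face_tree(self) -> cKDTree:
        if self._face_tree is None:
            centroids = self.coordinates[self.faces].mean(axis=1)
            self._face_tree = cKDTree(centroids)
        return self._face_tree

    def with_coordinates(self, coords: np.ndarray) -> "FlatMap":
        """Same combinatorial mesh at new vertex positions (no reorientation)."""
        out = FlatMap.__new__(FlatMap)
        out.coordinates = np.asarray(coords, dtype=float)
        out.faces = self.faces
        out.degenerate_faces = self.degenerate_faces
        out.edges = self.edges
        out.angle_triples = self.angle_triples
        out.perimeter = self.perimeter
        out.mean_edge_length = float(
            edge_lengths(out.coordinates, self.edges).mean())
        out.fields = dict(self.fields)
        out._face_tree = None
        return out


def orthographic_project(mesh: Mesh3D, proj: MapProjection,
                         sphere_tol: float = 1e-3) -> FlatMap:
    """Orthographically project a spherical mesh to a 2D flat map.

    Vertices within ``proj.radius_deg`` of the projection center are kept;
    the retained coordinates are the in-plane (x, y) components after the
    rotation taking the center to the pole, on the sphere's own radius scale.
    Faces are kept only when all three vertices are kept.  Left-hemisphere
    maps are mirrored so both hemispheres share one orientation convention.
    """
    v = mesh.vertices
    r = np.linalg.norm(v, axis=1)
    r0 = r.mean()
    if r0 <= 0 or np.max(np.abs(r - r0)) > sphere_tol * max(r0, 1.0):
        raise MeshError("input mesh does not lie on a sphere "
                        f"(radial deviation {np.max(np.abs(r - r0)):.3g})")
    unit = v / r[:, None]
    rot = proj.rotation()
    u = unit @ rot.T
    ang = np.degrees(np.arccos(np.clip(u[:, 2], -1.0, 1.0)))
    keep = ang <= proj.radius_deg + 1e-12
    if not keep.any():
        raise MeshError("empty selection: no vertex within the projection radius")
    new_index = -np.ones(len(v), dtype=np.intp)
    new_index[keep] = np.arange(keep.sum())
    fkeep = keep[mesh.faces].all(axis=1)
    if not fkeep.any():
        raise MeshError("empty selection: no face within the projection radius")
    faces = new_index[mesh.faces[fkeep]]
    coords = u[keep][:, :2] * r0
    if proj.chirality == "lh":
        coords = coords * np.array([-1.0, 1.0])
    fields = {k: np.asarray(val)[keep] for k, val in mesh.fields.items()}
    fm = FlatMap(coords, faces, fields=fields)
    fm.projection = proj
    fm.vertex_ids = np.flatnonzero(keep)  # indices into the source mesh
    return fm


def edge_lengths(coords: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Euclidean length of every edge (u, v): ``r_x(u, v)``."""
    d = coords[edges[:, 0]] - coords[edges[:, 1]]
    return np.sqrt((d * d).sum(axis=1))


def corner_angles(coords: np.ndarray, triples: np.ndarray) -> np.ndarray:
    """CCW angle at vertex a between (b - a) and (c - a), in [0, 2π).

    Raises on a zero-length incident edge, which leaves the angle undefined.
    """
    a, b, c = (coords[triples[:, i]] for i in range(3))
    u = b - a
    w = c - a
    nu = np.sqrt((u * u).sum(axis=1))
    nw = np.sqrt((w * w).sum(axis=1))
    if np.any(nu == 0) or np.any(nw == 0):
        raise MeshError("degenerate geometry: zero-length edge at a corner")
    ang = np.arctan2(u[:, 0] * w[:, 1] - u[:, 1] * w[:, 0],
                     (u * w).sum(axis=1))
    return np.mod(ang, 2 * np.pi)


def triangle_field_sign(flat_coords: np.ndarray,
                        visual_coords: np.ndarray,
                        faces: np.ndarray) -> np.ndarray:
    """Field sign per face: mirror (-1) vs non-mirror (+1) visual-field image.

    The sign of the face's signed area in the visual field times the sign of
    its signed area on the map; 0 for degenerate images.  Faces with any
    non-finite visual-field coordinate get NaN (excluded, not an error).
    """
    sa_map = _signed_areas(flat_coords, faces)
    sa_vis = _signed_areas(np.asarray(visual_coords, dtype=float), faces)
    out = np.sign(sa_vis) * np.sign(sa_map)
    bad = ~np.isfinite(visual_coords[faces]).all(axis=(1, 2))
    out[np.abs(sa_vis) < DEGENERATE_AREA] = 0.0
    out[bad] = np.nan
    return out


def vertex_surface_areas(mesh: Mesh3D) -> np.ndarray:
    """Per-vertex surface area (mm²): one third of each incident face's area.

    Conserves total area: the vertex areas sum to the summed face areas.
    """
    a = mesh.vertices[mesh.faces[:, 0]]
    b = mesh.vertices[mesh.faces[:, 1]]
    c = mesh.vertices[mesh.faces[:, 2]]
    fa = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
    out = np.zeros(mesh.n_vertices)
    np.add.at(out, mesh.faces.ravel(), np.repeat(fa / 3.0, 3))
    return out


def _barycentric(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Barycentric coordinates of ``points`` (k, 2) in triangles ``tri`` (k, 3, 2)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    v0 = b - a
    v1 = c - a
    v2 = points - a
    den = v0[:, 0] * v1[:, 1] - v1[:, 0] * v0[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        l1 = (v2[:, 0] * v1[:, 1] - v1[:, 0] * v2[:, 1]) / den
        l2 = (v0[:, 0] * v2[:, 1] - v2[:, 0] * v0[:, 1]) / den
    return np.stack([1.0 - l1 - l2, l1, l2], axis=1)


def locate_points(fm: FlatMap, points: np.ndarray,
                  tol: float = 1e-10, k: int = 24) -> tuple[np.ndarray, np.ndarray]:
    """Find the containing face for each 2D query point.

    Returns ``(face_index, barycentric_weights)``; face_index is -1 for
    points outside every face.  Ties (a point on a shared edge) resolve to
    the lowest face index, so lookups are deterministic.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    face_idx = np.full(n, -1, dtype=np.intp)
    bary = np.full((n, 3), np.nan)
    if n == 0:
        return face_idx, bary
    tree = fm.face_tree()
    kk = min(k, len(fm.faces))
    _, cand = tree.query(pts, k=kk)
    cand = np.atleast_2d(cand.T).T if cand.ndim == 1 else cand
    tris = fm.coordinates[fm.faces]
    unresolved = np.arange(n)
    # nearest-centroid candidates first, sorted so the lowest face index wins
    cand_sorted = np.sort(cand, axis=1)
    for j in range(cand_sorted.shape[1]):
        if unresolved.size == 0:
            break
        f = cand_sorted[unresolved, j]
        lam = _barycentric(pts[unresolved], tris[f])
        inside = np.isfinite(lam).all(axis=1) & (lam.min(axis=1) >= -tol)
        hit = unresolved[inside]
        face_idx[hit] = f[inside]
        bary[hit] = np.clip(lam[inside], 0.0, None)
        unresolved = unresolved[~inside]
    if unresolved.size:
        # exhaustive fallback for points far from any centroid neighbourhood
        for i in unresolved:
            lam = _barycentric(np.broadcast_to(pts[i], (len(tris), 2)), tris)
            ok = np.isfinite(lam).all(axis=1) & (lam.min(axis=1) >= -tol)
            hits = np.flatnonzero(ok)
            if hits.size:
                face_idx[i] = hits[0]
                bary[i] = np.clip(lam[hits[0]], 0.0, None)
    good = face_idx >= 0
    if good.any():
        s = bary[good].sum(axis=1, keepdims=True)
        bary[good] = bary[good] / s
    return face_idx, bary


def barycentric_interpolate(fm: FlatMap, values: np.ndarray,
                            points: np.ndarray,
                            missing: float = np.nan) -> np.ndarray:
    """Linearly interpolate per-vertex ``values`` at 2D ``points``.

    Points outside every face receive ``missing``.  ``values`` may be (n,)
    or (n, d).  Angular quantities must be embedded (e.g. as visual-field
    Cartesian coordinates) before interpolation; this function is linear.
    """
    values = np.asarray(values, dtype=float)
    face_idx, bary = locate_points(fm, points)
    vals = values[fm.faces]          # (m, 3) or (m, 3, d)
    shape = (len(face_idx),) + values.shape[1:]
    out = np.full(shape, missing, dtype=float)
    good = face_idx >= 0
    if good.any():
        v = vals[face_idx[good]]
        w = bary[good]
        if values.ndim == 1:
            out[good] = (v * w).sum(axis=1)
        else:
            out[good] = (v * w[:, :, None]).sum(axis=1)
    return out


def uniform_resample(fm: FlatMap, resolution: float,
                     fields: dict | None = None) -> FlatMap:
    """Resample a flat map onto a uniform equilateral-lattice triangulation.

    A regular triangular lattice with edge length ``resolution`` is laid over
    the source map's bounding box; lattice vertices falling inside the source
    mesh are kept, faces whose three corners are kept survive, and per-vertex
    fields are transferred by barycentric interpolation.
    """
    if resolution <= 0:
        raise MeshError("resolution must be positive")
    lo = fm.coordinates.min(axis=0)
    hi = fm.coordinates.max(axis=0)
    dy = resolution * np.sqrt(3) / 2
    nrow = int(np.floor((hi[1] - lo[1]) / dy)) + 1
    ncol = int(np.floor((hi[0] - lo[0]) / resolution)) + 2
    if nrow < 2 or ncol < 2:
        raise MeshError("resolution larger than the map extent")
    verts = []
    index = {}
    for i in range(nrow):
        xoff = 0.5 * resolution * (i % 2)
        for j in range(ncol):
            index[(i, j)] = len(verts)
            verts.append((lo[0] + j * resolution - xoff, lo[1] + i * dy))
    verts = np.array(verts)
    faces = []
    for i in range(nrow - 1):
        for j in range(ncol - 1):
            a, b = index[(i, j)], index[(i, j + 1)]
            c, d = index[(i + 1, j)], index[(i + 1, j + 1)]
            if i % 2 == 0:
                # next row is shifted left: apex vertices straddle (a, b)
                faces.append((a, b, d))
                faces.append((a, d, c))
            else:
                faces.append((a, b, c))
                faces.append((b, d, c))
    faces = np.array(faces, dtype=np.intp)
    face_idx, _ = locate_points(fm, verts)
    keep = face_idx >= 0
    if keep.sum() < 3:
        raise MeshError("resolution larger than the map extent")
    new_index = -np.ones(len(verts), dtype=np.intp)
    new_index[keep] = np.arange(keep.sum())
    fkeep = keep[faces].all(axis=1)
    if not fkeep.any():
        raise MeshError("resolution larger than the map extent")
    out_faces = new_index[faces[fkeep]]
    out_coords = verts[keep]
    used = np.zeros(len(out_coords), dtype=bool)
    used[out_faces.ravel()] = True
    remap = -np.ones(len(out_coords), dtype=np.intp)
    remap[used] = np.arange(used.sum())
    out = FlatMap(out_coords[used], remap[out_faces])
    src_fields = dict(fm.fields)
    if fields:
        src_fields.update(fields)
    for name, vals in src_fields.items():
        out.fields[name] = barycentric_interpolate(fm, np.asarray(vals, float),
                                                   out.coordinates)
    return out
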