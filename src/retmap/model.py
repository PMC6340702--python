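"""2D retinotopy models: field fill-in between labeled boundaries, rescaling,
point lookup, and JSON (de)serialization.

A retinotopy model assigns a polar angle, an eccentricity and a visual-area
label to every point of a model region of the flattened cortical surface.
Models are built from hand-labeled (or generated) boundary contours: the
field values implied by each contour label are clamped on the nearest mesh
vertices and the interior is filled by minimizing

    f(theta, rho) = (theta . rho)^2
                  + sum_{(u,v) in E} [ (theta_u - theta_v)^2
                                      + (rho_u - rho_v)^2 ] / (2 ||x_u - x_v||)

over the scaled fields (both in [-1, 1]): the fields should be as smooth as
possible along mesh edges and as orthogonal to each other as possible.  Each
field's subproblem is a sparse linear solve; the two are alternated to a
joint gradient tolerance and the objective is non-increasing by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import brentq
from scipy.sparse.linalg import splu

from .mesh import FlatMap, edge_lengths, locate_points
from .visual import visual_field_angles, visual_field_coords

__all__ = [
    "BOUNDARY_LABELS",
    "VISUAL_AREAS",
    "BoundaryContour",
    "BoundarySpec",
    "RetinotopyModel",
    "build_model",
    "rescale_fields",
    "fit_eccentricity_rescale",
    "model_lookup",
    "serialize_model",
    "deserialize_model",
]

SCHEMA_VERSION = 1

#: The five boundary categories and the scaled field value each one clamps.
#: Vertical meridians clamp scaled polar angle (upper -1, lower +1), the
#: horizontal meridian clamps it to 0; foveal / peripheral contours clamp
#: scaled eccentricity to -1 / +1.
BOUNDARY_LABELS = {
    "foveal": ("rho", -1.0),
    "peripheral": ("rho", +1.0),
    "upper_vertical_meridian": ("theta", -1.0),
    "lower_vertical_meridian": ("theta", +1.0),
    "horizontal_meridian": ("theta", 0.0),
}

VISUAL_AREAS = ("V1", "V2", "V3", "hV4", "VO1", "VO2",
                "V3a", "V3b", "LO1", "LO2", "TO1", "TO2")
NO_AREA = "none"


class ModelError(ValueError):
    pass


@dataclass
class BoundaryContour:
    """One labeled boundary polyline.

    ``areas`` names the visual areas the contour touches (one for outer
    boundaries, two for a shared border).
    """

    points: np.ndarray           # (k, 2) polyline on the model mesh
    label: str                   # one of BOUNDARY_LABELS
    areas: tuple = ()

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.label not in BOUNDARY_LABELS:
            raise ModelError(f"unknown boundary label {self.label!r}")
        self.areas = tuple(self.areas)


@dataclass
class BoundarySpec:
    """Labeled boundary contours plus the area polygons they enclose."""

    contours: list
    area_polygons: dict          # area name -> (k, 2) closed polygon
    field_sign: dict = field(default_factory=dict)  # area -> +1 / -1
    prf_size_params: dict = field(default_factory=dict)  # area -> (m, b)

    def validate(self) -> None:
        for area in self.area_polygons:
            if area not in VISUAL_AREAS:
                raise ModelError(f"unknown visual area {area!r}")
            poly = np.asarray(self.area_polygons[area], dtype=float)
            if len(poly) < 3:
                raise ModelError(f"area {area!r} polygon is not a cycle")
            touching = [c for c in self.contours if area in c.areas]
            kinds = {BOUNDARY_LABELS[c.label][0] for c in touching}
            if kinds != {"theta", "rho"}:
                raise ModelError(
                    f"area {area!r} is not enclosed: needs both meridian "
                    "(angle) and foveal/peripheral (eccentricity) contours")


def points_in_polygon(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Even-odd-rule point-in-polygon test, vectorized over points.

    Points on an edge count as inside (within floating tolerance of the
    crossing rule); used only for coarse area labeling.
    """
    pts = np.asarray(points, dtype=float)
    poly = np.asarray(polygon, dtype=float)
    n = len(poly)
    inside = np.zeros(len(pts), dtype=bool)
    x, y = pts[:, 0], pts[:, 1]
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        cross = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cross & (x < np.where(cross, xint, np.inf))
    return inside


def _snap_to_vertices(mesh: FlatMap, points: np.ndarray) -> np.ndarray:
    """Nearest mesh vertex for each contour point; ties -> lowest index."""
    d2 = ((mesh.coordinates[None, :, :] - points[:, None, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def _densify(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at spacing <= step so snapping misses no vertex."""
    out = [points[0]]
    for a, b in zip(points[:-1], points[1:]):
        seg = np.linalg.norm(b - a)
        n = max(int(np.ceil(seg / step)), 1)
        for t in np.linspace(0, 1, n + 1)[1:]:
            out.append(a + t * (b - a))
    return np.array(out)


def _alternating_fill(mesh: FlatMap,
                      theta_fixed: np.ndarray, theta_values: np.ndarray,
                      rho_fixed: np.ndarray, rho_values: np.ndarray,
                      grad_tol: float = 1e-8,
                      max_iter: int = 200):
    """Minimize the orthogonality-plus-smoothness objective.

    Each half-step solves exactly for one field given the other (a sparse
    SPD system, with the rank-one orthogonality coupling folded in by the
    Sherman-Morrison identity), so the joint objective never increases.
    Returns (theta, rho, objective trajectory).
    """
    n = mesh.n_vertices
    E = mesh.edges
    w = 1.0 / (2.0 * edge_lengths(mesh.coordinates, E))
    if not np.all(np.isfinite(w)):
        raise ModelError("zero-length edge in model mesh")
    # graph Laplacian of the smoothness term: S(f) = f^T L f
    i, j = E[:, 0], E[:, 1]
    L = sparse.coo_matrix(
        (np.concatenate([w, w, -w, -w]),
         (np.concatenate([i, j, i, j]), np.concatenate([i, j, j, i]))),
        shape=(n, n)).tocsc()

    def setup(fixed):
        free = ~fixed
        lu = splu(L[free][:, free].tocsc())
        return free, lu, L[free][:, fixed.nonzero()[0]]

    th = np.zeros(n)
    rh = np.zeros(n)
    th[theta_fixed] = theta_values[theta_fixed]
    rh[rho_fixed] = rho_values[rho_fixed]
    free_t, lu_t, Ltb = setup(theta_fixed)
    free_r, lu_r, Lrb = setup(rho_fixed)

    def objective(t, r):
        st = t[E[:, 0]] - t[E[:, 1]]
        sr = r[E[:, 0]] - r[E[:, 1]]
        return float(np.dot(t, r) ** 2 + (w * (st**2 + sr**2)).sum())

    def solve_field(lu, Lfb, free, fixed, fvals, other):
        # minimize (f.other)^2 + f^T L f over the free entries:
        #   (L_ff + p p^T) f_free = -L_fb f_fixed - (other_fixed . f_fixed') p
        # where p = other_free; Sherman-Morrison against the L_ff factor.
        p = other[free]
        b = -Lfb @ fvals[fixed] - float(other[fixed] @ fvals[fixed]) * p
        x0 = lu.solve(b)
        z = lu.solve(p)
        denom = 1.0 + float(p @ z)
        return x0 - z * (float(p @ x0) / denom)

    def gradient(t, r):
        d = np.dot(t, r)
        return 2 * d * r + 2 * (L @ t), 2 * d * t + 2 * (L @ r)

    def gnorm_of(t, r):
        g_t, g_r = gradient(t, r)
        return np.sqrt((g_t[free_t] ** 2).sum() + (g_r[free_r] ** 2).sum())

    traj = [objective(th, rh)]
    # alternating exact block solves: cheap, monotone, excellent start
    for _ in range(3):
        th[free_t] = solve_field(lu_t, Ltb, free_t, theta_fixed,
                                 theta_values, rh)
        rh[free_r] = solve_field(lu_r, Lrb, free_r, rho_fixed,
                                 rho_values, th)
        traj.append(objective(th, rh))
        if gnorm_of(th, rh) < grad_tol:
            return th, rh, np.array(traj)
    # damped Newton refinement: block descent stalls in the valley of the
    # orthogonality term (its Hessian is sparse + rank one), while Newton
    # with a Sherman-Morrison solve converges quadratically
    mask = np.concatenate([free_t, free_r])
    nfree = int(mask.sum())
    gnorm = gnorm_of(th, rh)
    for _ in range(max_iter):
        if gnorm < grad_tol:
            break
        d = np.dot(th, rh)
        g_t, g_r = gradient(th, rh)
        g = np.concatenate([g_t, g_r])[mask]
        S = sparse.bmat([[2 * L, 2 * d * sparse.eye(n, format="csc")],
                         [2 * d * sparse.eye(n, format="csc"), 2 * L]],
                        format="csc")
        S = S[mask][:, mask].tocsc()
        v = np.concatenate([rh, th])[mask]
        lu = splu(S)
        y = lu.solve(-g)
        z = lu.solve(v)
        denom = 1.0 + 2.0 * float(v @ z)
        step = y - z * (2.0 * float(v @ y) / denom)
        # backtracking line search keeps the objective non-increasing
        f0 = objective(th, rh)
        alpha = 1.0
        for _ls in range(30):
            t_new = th.copy()
            r_new = rh.copy()
            t_new[free_t] = th[free_t] + alpha * step[:free_t.sum()]
            r_new[free_r] = rh[free_r] + alpha * step[free_t.sum():]
            if objective(t_new, r_new) <= f0 + 1e-15 * max(1.0, abs(f0)):
                th, rh = t_new, r_new
                break
            alpha *= 0.5
        else:
            break
        traj.append(objective(th, rh))
        gnorm = gnorm_of(th, rh)
    if gnorm >= grad_tol:
        raise ModelError(
            f"field fill did not converge: residual gradient {gnorm:.3g}")
    return th, rh, np.array(traj)


def fit_eccentricity_rescale(raw: np.ndarray,
                             targets=(0.0, 3.0, 90.0)) -> dict:
    """Fit the two-parameter exponential eccentricity rescaling.

    Maps scaled eccentricity ``s = (raw + 1)/2`` in [0, 1] to degrees via
    ``rho = t_min + a*(exp(b*s) - 1)`` with (a, b) chosen so that the raw
    field's minimum, median and maximum land on ``targets`` (deg).
    """
    t_min, t_med, t_max = map(float, targets)
    if not (t_min < t_med < t_max):
        raise ModelError("eccentricity targets must be increasing")
    s = (np.asarray(raw, dtype=float) + 1.0) / 2.0
    s_med = float(np.median(s))
    if not (0.0 < s_med < 1.0):
        raise ModelError("degenerate raw eccentricity field")
    span = t_max - t_min
    frac = (t_med - t_min) / span

    def eqn(b):
        # (exp(b*s_med)-1)/(exp(b)-1) - frac, continuous at b=0 (limit s_med)
        if abs(b) < 1e-9:
            return s_med - frac
        return np.expm1(b * s_med) / np.expm1(b) - frac

    if abs(eqn(0.0)) < 1e-12:
        b = 0.0
    else:
        lo, hi = -50.0, 50.0
        if eqn(lo) * eqn(hi) > 0:
            raise ModelError("eccentricity rescale parameters not solvable")
        b = brentq(eqn, lo, hi, xtol=1e-12)
    a = span / np.expm1(b) if abs(b) >= 1e-9 else span
    params = {"t_min": t_min, "a": float(a), "b": float(b)}
    # monotonicity of the fitted map
    test = apply_eccentricity_rescale(np.linspace(-1, 1, 101), params)
    if np.any(np.diff(test) <= 0):
        raise ModelError("fitted eccentricity map is not strictly increasing")
    return params


def apply_eccentricity_rescale(raw, params) -> np.ndarray:
    s = (np.asarray(raw, dtype=float) + 1.0) / 2.0
    a, b, t_min = params["a"], params["b"], params["t_min"]
    if abs(b) < 1e-9:
        return t_min + a * s
    return t_min + a * np.expm1(b * s)


def rescale_fields(theta_raw, rho_raw, ecc_targets=(0.0, 3.0, 90.0)):
    """Rescale the scaled [-1, 1] fields to degrees.

    Polar angle is linear: theta = 90*(raw + 1), so -1 -> 0 deg (upper
    vertical meridian) and +1 -> 180 deg.  Eccentricity uses the fitted
    exponential map (see :func:`fit_eccentricity_rescale`).
    Returns (theta deg, rho deg, eccentricity rescale params).
    """
    theta_raw = np.asarray(theta_raw, dtype=float)
    rho_raw = np.asarray(rho_raw, dtype=float)
    params = fit_eccentricity_rescale(rho_raw, ecc_targets)
    return 90.0 * (theta_raw + 1.0), apply_eccentricity_rescale(rho_raw, params), params


# default linear pRF-size-vs-eccentricity parameters (slope, intercept), deg
DEFAULT_PRF_SIZE_PARAMS = {
    "V1": (0.10, 0.30), "V2": (0.15, 0.40), "V3": (0.20, 0.50),
    "hV4": (0.25, 0.60), "VO1": (0.27, 0.70), "VO2": (0.29, 0.80),
    "V3a": (0.25, 0.60), "V3b": (0.26, 0.65), "LO1": (0.28, 0.70),
    "LO2": (0.30, 0.80), "TO1": (0.32, 0.90), "TO2": (0.34, 1.00),
}


class RetinotopyModel:
    """A built model: mesh + per-vertex (theta, rho, area) + metadata.

    ``theta`` is polar angle in [0, 180] deg within the hemifield; ``rho``
    is eccentricity in [0, 90] deg; ``area`` is a per-vertex label string
    ('none' outside every area).  ``face_areas`` labels each face (by its
    centroid), which is what point lookups report.
    """

    def __init__(self, mesh: FlatMap, theta: np.ndarray, rho: np.ndarray,
                 area: np.ndarray, rescale_params: dict,
                 area_polygons: dict, field_sign: dict | None = None,
                 prf_size_params: dict | None = None):
        self.mesh = mesh
        self.theta = np.asarray(theta, dtype=float)
        self.rho = np.asarray(rho, dtype=float)
        self.area = np.asarray(area, dtype=object)
        self.rescale_params = dict(rescale_params)
        self.area_polygons = {k: np.asarray(v, dtype=float)
                              for k, v in area_polygons.items()}
        self.field_sign = dict(field_sign or {})
        self.prf_size_params = {
            k: tuple(prf_size_params.get(k, DEFAULT_PRF_SIZE_PARAMS[k]))
            if prf_size_params else DEFAULT_PRF_SIZE_PARAMS[k]
            for k in self.area_polygons}
        if np.any(self.theta < -1e-9) or np.any(self.theta > 180 + 1e-9):
            raise ModelError("model polar angle outside [0, 180] deg")
        if np.any(self.rho < -1e-9) or np.any(self.rho > 90 + 1e-9):
            raise ModelError("model eccentricity outside [0, 90] deg")
        centroids = self.mesh.coordinates[self.mesh.faces].mean(axis=1)
        self.face_areas = np.array([NO_AREA] * len(self.mesh.faces),
                                   dtype=object)
        for name, poly in self.area_polygons.items():
            hit = points_in_polygon(centroids, poly)
            self.face_areas[hit] = name
        # visual-field embedding used for all interpolation of the fields
        self.visual_coords = visual_field_coords(self.theta, self.rho, "lh")
        if not self.field_sign:
            # majority face sign per area, computed from the model itself
            from .mesh import triangle_field_sign
            fs = triangle_field_sign(self.mesh.coordinates,
                                     self.visual_coords, self.mesh.faces)
            for name in self.area_polygons:
                sel = (self.face_areas == name) & np.isfinite(fs)
                if sel.any():
                    self.field_sign[name] = float(np.sign(fs[sel].sum()))

    @property
    def areas(self) -> tuple:
        return tuple(self.area_polygons)

    def prf_size_at(self, area: str, rho) -> np.ndarray:
        m, b = self.prf_size_params[area]
        return m * np.asarray(rho, dtype=float) + b

    def area_field_sign(self, area: str) -> float:
        return self.field_sign.get(area, 0.0)


def build_model(spec: BoundarySpec, mesh: FlatMap,
                ecc_targets=(0.0, 3.0, 90.0),
                grad_tol: float = 1e-8) -> RetinotopyModel:
    """Build a retinotopy model from labeled boundary contours on a mesh.

    Contour points are snapped to the nearest mesh vertices; the label's
    implied scaled value is clamped there; interior fields are filled by the
    alternating minimization and rescaled to degrees.
    """
    spec.validate()
    n = mesh.n_vertices
    theta_fixed = np.zeros(n, dtype=bool)
    theta_values = np.zeros(n)
    rho_fixed = np.zeros(n, dtype=bool)
    rho_values = np.zeros(n)
    step = 0.5 * mesh.mean_edge_length
    for contour in spec.contours:
        which, value = BOUNDARY_LABELS[contour.label]
        pts = (_densify(contour.points, step)
               if len(contour.points) > 1 else contour.points)
        idx = np.unique(_snap_to_vertices(mesh, pts))
        if which == "theta":
            theta_fixed[idx] = True
            theta_values[idx] = value
        else:
            rho_fixed[idx] = True
            rho_values[idx] = value
    if not theta_fixed.any() or not rho_fixed.any():
        raise ModelError("boundary spec fixes no vertices for some field")
    th, rh, traj = _alternating_fill(mesh, theta_fixed, theta_values,
                                     rho_fixed, rho_values, grad_tol=grad_tol)
    th = np.clip(th, -1.0, 1.0)
    rh = np.clip(rh, -1.0, 1.0)
    theta_deg, rho_deg, params = rescale_fields(th, rh, ecc_targets)
    area = np.array([NO_AREA] * n, dtype=object)
    for name, poly in spec.area_polygons.items():
        hit = points_in_polygon(mesh.coordinates, poly)
        area[hit & (area == NO_AREA)] = name
    model = RetinotopyModel(mesh, theta_deg, rho_deg, area, params,
                            spec.area_polygons, field_sign=spec.field_sign,
                            prf_size_params=spec.prf_size_params or None)
    model.fill_objective_trajectory = traj
    return model


def model_lookup(model: RetinotopyModel, points: np.ndarray):
    """(theta deg, rho deg, area label) of the model at 2D map points.

    The label is the area of the containing face ('none' outside all
    areas); fields are barycentric-interpolated through the visual-field
    Cartesian embedding, so polar angle never suffers wrap artifacts.
    Outside the mesh, fields are NaN.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    face_idx, bary = locate_points(model.mesh, points)
    labels = np.array([NO_AREA] * len(points), dtype=object)
    good = face_idx >= 0
    labels[good] = model.face_areas[face_idx[good]]
    vc = np.full((len(points), 2), np.nan)
    if good.any():
        corners = model.visual_coords[model.mesh.faces[face_idx[good]]]
        vc[good] = (corners * bary[good][:, :, None]).sum(axis=1)
    theta, rho = visual_field_angles(vc, "lh")
    theta = np.where(good, theta, np.nan)
    rho = np.where(good, rho, np.nan)
    return theta, rho, labels


def serialize_model(model: RetinotopyModel) -> str:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "mesh": {
            "coordinates": model.mesh.coordinates.tolist(),
            "faces": model.mesh.faces.tolist(),
        },
        "theta_deg": model.theta.tolist(),
        "rho_deg": model.rho.tolist(),
        "area": list(model.area),
        "rescale_params": model.rescale_params,
        "area_polygons": {k: v.tolist() for k, v in model.area_polygons.items()},
        "field_sign": model.field_sign,
        "prf_size_params": {k: list(v) for k, v in model.prf_size_params.items()},
    }
    return json.dumps(doc)


def deserialize_model(text: str) -> RetinotopyModel:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelError(f"model JSON is not parseable: {exc}") from None
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ModelError(
            f"model schema version {doc.get('schema_version')!r} != "
            f"{SCHEMA_VERSION}")
    for key in ("mesh", "theta_deg", "rho_deg", "area",
                "rescale_params", "area_polygons"):
        if key not in doc:
            raise ModelError(f"model JSON missing section {key!r}")
    mesh = FlatMap(np.array(doc["mesh"]["coordinates"]),
                   np.array(doc["mesh"]["faces"]), fix_orientation=False)
    return RetinotopyModel(
        mesh,
        np.array(doc["theta_deg"], dtype=float),
        np.array(doc["rho_deg"], dtype=float),
        np.array(doc["area"], dtype=object),
        doc["rescale_params"],
        {k: np.array(v) for k, v in doc["area_polygons"].items()},
        field_sign=doc.get("field_sign"),
        prf_size_params={k: tuple(v)
                         for k, v in doc.get("prf_size_params", {}).items()}
        or None,
    )
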