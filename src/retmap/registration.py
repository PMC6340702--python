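"""Topology-preserving registration of a flattened cortical map to a
retinotopy model.

The registered coordinates minimize a potential

    F(x) = Fe(x) + Ftheta(x) + Fp(x) + Fphi(x)

whose first three terms penalize deformation away from the reference
configuration x0 (edge lengths, corner angles, perimeter positions) and
whose last term is a sum of inverted-Gaussian wells ("anchors") attracting
each measured vertex toward the model positions that share its measured
retinotopic coordinates.  The edge and angle terms each combine a harmonic
penalty with an infinite-well barrier that diverges as an edge length
approaches its allowed bounds (q0, q1) or a corner angle approaches 0 or pi;
together with a minimizer that backtracks whenever a proposed step crosses
one of these singularities, this guarantees that no mesh triangle ever
inverts, so the registered map preserves the topology of the model.

Maximizing exp(-F) is the Bayesian reading of the minimization: the
deformation terms are the log-prior over warps of the reference mesh and the
anchor term is the log-likelihood of the retinotopic measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import FlatMap, corner_angles, edge_lengths, triangle_field_sign
from .visual import visual_field_coords

__all__ = [
    "RegistrationSystem",
    "AnchorSet",
    "MinimizerConfig",
    "RegistrationResult",
    "AnchorWeightConfig",
    "SingularityError",
    "build_anchors",
    "edge_potential",
    "angle_potential",
    "perimeter_potential",
    "anchor_potential",
    "total_potential",
    "total_gradient",
    "minimize",
]


class SingularityError(RuntimeError):
    """A configuration at or beyond an edge-length or angle singularity."""


class RegistrationSystem:
    """Reference configuration plus the structure the potential needs.

    ``q0``/``q1`` bound the allowable edge lengths: by default edges may
    shrink toward 0 (q0 = 0) and at most double (q1 = 2 * reference length,
    per edge).  The reference must be strictly admissible.
    """

    def __init__(self, reference: FlatMap, q0: float = 0.0,
                 q1_factor: float = 2.0, q1: np.ndarray | None = None):
        self.reference = reference
        self.x0 = reference.coordinates.copy()
        self.edges = reference.edges
        self.triples = reference.angle_triples
        self.perimeter = reference.perimeter
        self.epsilon = reference.mean_edge_length
        self.r0 = edge_lengths(self.x0, self.edges)
        self.a0 = corner_angles(self.x0, self.triples)
        self.q0 = float(q0)
        self.q1 = (np.asarray(q1, dtype=float) if q1 is not None
                   else q1_factor * self.r0)
        if np.any(self.r0 <= self.q0) or np.any(self.r0 >= self.q1):
            raise ValueError("reference edge lengths must lie strictly "
                             "inside (q0, q1)")
        if np.any(self.a0 <= 0) or np.any(self.a0 >= np.pi):
            raise ValueError("reference corner angles must lie in (0, pi)")
        self.n_vertices = reference.n_vertices


@dataclass
class AnchorSet:
    """The anchors Phi: vertex u drawn toward point y with well width sigma."""

    vertex: np.ndarray   # (k,) int
    point: np.ndarray    # (k, 2) float
    sigma: np.ndarray    # (k,) float, > 0
    weight: np.ndarray   # (k,) float, >= 0
    area: np.ndarray = None  # (k,) object, the target area of each anchor

    def __post_init__(self) -> None:
        self.vertex = np.asarray(self.vertex, dtype=np.intp)
        self.point = np.asarray(self.point, dtype=float).reshape(-1, 2)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        if self.area is None:
            self.area = np.array(["?"] * len(self.vertex), dtype=object)
        if len(self.vertex) and (np.any(self.sigma <= 0)
                                 or np.any(self.weight < 0)):
            raise ValueError("anchor sigma must be > 0 and weight >= 0")

    def __len__(self) -> int:
        return len(self.vertex)

    @classmethod
    def empty(cls) -> "AnchorSet":
        return cls(np.empty(0, dtype=np.intp), np.empty((0, 2)),
                   np.empty(0), np.empty(0))


@dataclass
class MinimizerConfig:
    """Gradient-descent schedule.

    ``max_step`` caps the per-vertex displacement per step; when None it
    defaults to epsilon/50 (one fiftieth of the reference mean edge
    length).  ``noise_scale`` sets the exponentially distributed
    multiplicative gradient noise: each vertex's gradient magnitude is
    scaled by (1 + Exp(1) * noise_scale), direction preserved; the default
    1.0 makes the median factor about 1.7.  A step is accepted only if it
    stays admissible and does not increase the potential; otherwise it is
    retried at ``backtrack_factor`` times the size.
    """

    steps: int = 2500
    max_step: float | None = None
    noise_scale: float = 1.0
    backtrack_factor: float = 0.5
    max_backtracks: int = 50
    seed: int = 0
    grad_tol: float = 0.0   # optional early stop; 0 disables

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.max_step is not None and not self.max_step > 0:
            raise ValueError("max_step must be positive")
        if not (0.0 < self.backtrack_factor < 1.0):
            raise ValueError("backtrack_factor must lie in (0, 1)")


@dataclass
class RegistrationResult:
    coordinates: np.ndarray        # registered x*
    potential: np.ndarray          # per accepted step (index 0 = start)
    backtracks: int
    final_gradient_norm: float
    skipped_steps: int = 0
    # per-step admissibility extrema: (min angle, max angle, min edge/q1
    # margin as min(r - q0), max r/q1); rows align with `potential`
    admissibility: np.ndarray | None = None


# ---------------------------------------------------------------- potentials

def _scatter_add(grad: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
    """grad[idx] += vals with repeated indices (bincount; faster than add.at)."""
    n = len(grad)
    grad[:, 0] += np.bincount(idx, weights=vals[:, 0], minlength=n)
    grad[:, 1] += np.bincount(idx, weights=vals[:, 1], minlength=n)


def _edge_quantities(x, sys):
    d = x[sys.edges[:, 0]] - x[sys.edges[:, 1]]
    r = np.sqrt((d * d).sum(axis=1))
    return d, r


def edge_potential(x: np.ndarray, sys: RegistrationSystem):
    """Edge-length deviation term Fe = (He + Ge)/|E| and its gradient.

    He is the harmonic penalty 1/2 sum (r - r0)^2; Ge is the infinite-well
    barrier that diverges as r approaches q0 or q1.  Raises
    :class:`SingularityError` if any edge length is outside (q0, q1).
    """
    d, r = _edge_quantities(x, sys)
    if np.any(r <= sys.q0) or np.any(r >= sys.q1):
        raise SingularityError("edge length outside (q0, q1)")
    r0, q0, q1 = sys.r0, sys.q0, sys.q1
    A = (r0 - q0) / (r - q0) - 1.0
    B = (q1 - r0) / (q1 - r) - 1.0
    he = 0.5 * ((r - r0) ** 2).sum()
    ge = 0.5 * (A * A + B * B).sum()
    nE = len(sys.edges)
    value = (he + ge) / nE
    # d/dr of the summands
    dfdr = (r - r0) + A * (-(r0 - q0) / (r - q0) ** 2) \
        + B * ((q1 - r0) / (q1 - r) ** 2)
    unit = d / r[:, None]
    contrib = (dfdr / nE)[:, None] * unit
    grad = np.zeros_like(x)
    _scatter_add(grad, sys.edges[:, 0], contrib)
    _scatter_add(grad, sys.edges[:, 1], -contrib)
    return value, grad


def _angle_quantities(x, sys):
    t = sys.triples
    a, b, c = x[t[:, 0]], x[t[:, 1]], x[t[:, 2]]
    u = b - a
    w = c - a
    ang = np.arctan2(u[:, 0] * w[:, 1] - u[:, 1] * w[:, 0],
                     (u * w).sum(axis=1))
    ang = np.mod(ang, 2 * np.pi)
    return u, w, ang


def angle_potential(x: np.ndarray, sys: RegistrationSystem):
    """Corner-angle deviation term Ftheta = (Htheta + Gtheta)/|Theta|.

    Harmonic part 1/2 sum (alpha - alpha0)^2 plus a barrier diverging as
    any corner angle approaches 0 or pi.  Raises
    :class:`SingularityError` for angles outside (0, pi).
    """
    u, w, a = _angle_quantities(x, sys)
    if np.any(a <= 0) or np.any(a >= np.pi):
        raise SingularityError("corner angle outside (0, pi)")
    a0 = sys.a0
    A = a0 / a - 1.0
    B = (np.pi - a0) / (np.pi - a) - 1.0
    h = 0.5 * ((a - a0) ** 2).sum()
    g = 0.5 * (A * A + B * B).sum()
    nT = len(sys.triples)
    value = (h + g) / nT
    dfda = (a - a0) + A * (-a0 / a ** 2) + B * ((np.pi - a0) / (np.pi - a) ** 2)
    dfda = dfda / nT
    # dalpha/dx via the perpendicular-over-squared-norm rule
    nu2 = (u * u).sum(axis=1)
    nw2 = (w * w).sum(axis=1)
    perp_u = np.stack([-u[:, 1], u[:, 0]], axis=1) / nu2[:, None]
    perp_w = np.stack([-w[:, 1], w[:, 0]], axis=1) / nw2[:, None]
    gb = -perp_u * dfda[:, None]
    gc = perp_w * dfda[:, None]
    ga = -(gb + gc)
    grad = np.zeros_like(x)
    t = sys.triples
    _scatter_add(grad, t[:, 0], ga)
    _scatter_add(grad, t[:, 1], gb)
    _scatter_add(grad, t[:, 2], gc)
    return value, grad


def perimeter_potential(x: np.ndarray, sys: RegistrationSystem):
    """Fp = 1/2 sum over perimeter vertices of ||x_u - x0_u||^2."""
    P = sys.perimeter
    d = x[P] - sys.x0[P]
    value = 0.5 * (d * d).sum()
    grad = np.zeros_like(x)
    grad[P] = d
    return value, grad


def anchor_potential(x: np.ndarray, anchors: AnchorSet):
    """Fphi = -(1/|Phi|) sum w exp(-||x_u - y||^2 / sigma^2) and gradient.

    Negative because anchors are potential *wells*: the term decreases as a
    vertex approaches its anchor point.  Empty anchor sets contribute 0.
    """
    if len(anchors) == 0:
        return 0.0, np.zeros_like(x)
    d = x[anchors.vertex] - anchors.point
    r2 = (d * d).sum(axis=1)
    e = anchors.weight * np.exp(-r2 / anchors.sigma ** 2)
    nPhi = len(anchors)
    value = -e.sum() / nPhi
    coef = (2.0 * e / (anchors.sigma ** 2 * nPhi))[:, None]
    grad = np.zeros_like(x)
    _scatter_add(grad, anchors.vertex, coef * d)
    return value, grad


def total_potential(x, sys, anchors) -> float:
    return (edge_potential(x, sys)[0] + angle_potential(x, sys)[0]
            + perimeter_potential(x, sys)[0] + anchor_potential(x, anchors)[0])


def total_gradient(x, sys, anchors) -> np.ndarray:
    return (edge_potential(x, sys)[1] + angle_potential(x, sys)[1]
            + perimeter_potential(x, sys)[1] + anchor_potential(x, anchors)[1])


def _value_and_grad(x, sys, anchors):
    ve, ge = edge_potential(x, sys)
    va, ga = angle_potential(x, sys)
    vp, gp = perimeter_potential(x, sys)
    vf, gf = anchor_potential(x, anchors)
    return ve + va + vp + vf, ge + ga + gp + gf


# ---------------------------------------------------------------- minimizer

def minimize(sys: RegistrationSystem, anchors: AnchorSet,
             cfg: MinimizerConfig | None = None) -> RegistrationResult:
    """Noise-assisted, backtracking gradient descent on the potential.

    Each step proposes a displacement along the (noise-scaled) negative
    gradient, scaled so the largest per-vertex displacement equals
    ``max_step``.  Steps that cross a singularity (an inverted triangle or
    an out-of-bounds edge) or that increase the potential are retried at a
    fraction of the size; after ``max_backtracks`` retries the step is
    skipped.  With ``noise_scale = 0`` the potential sequence is strictly
    non-increasing and the trajectory is deterministic; with noise it is
    deterministic given the seed.
    """
    if cfg is None:
        cfg = MinimizerConfig()
    max_step = cfg.max_step if cfg.max_step is not None else sys.epsilon / 50.0
    rng = np.random.default_rng(cfg.seed)
    x = sys.x0.copy()
    f, g = _value_and_grad(x, sys, anchors)
    trajectory = [f]
    backtracks = 0
    skipped = 0

    def _admissibility(xc):
        _, r = _edge_quantities(xc, sys)
        _, _, a = _angle_quantities(xc, sys)
        return (float(a.min()), float(a.max()),
                float((r - sys.q0).min()), float((r / sys.q1).max()))

    admiss = [_admissibility(x)]
    for _ in range(cfg.steps):
        if cfg.noise_scale > 0:
            factor = 1.0 + rng.exponential(1.0, size=len(x)) * cfg.noise_scale
        else:
            factor = 1.0
        step_vec = -g * (factor if np.isscalar(factor) else factor[:, None])
        biggest = np.sqrt((step_vec * step_vec).sum(axis=1)).max()
        if biggest == 0.0:
            trajectory.append(f)
            continue
        scale = max_step / biggest
        accepted = False
        for _try in range(cfg.max_backtracks + 1):
            x_new = x + step_vec * scale
            try:
                f_new, g_new = _value_and_grad(x_new, sys, anchors)
            except SingularityError:
                scale *= cfg.backtrack_factor
                backtracks += 1
                continue
            if f_new <= f:
                x, f, g = x_new, f_new, g_new
                accepted = True
                break
            scale *= cfg.backtrack_factor
            backtracks += 1
        if not accepted:
            skipped += 1
        trajectory.append(f)
        admiss.append(_admissibility(x))
        if cfg.grad_tol > 0 and np.sqrt((g * g).sum()) < cfg.grad_tol:
            break
    return RegistrationResult(
        coordinates=x,
        potential=np.array(trajectory),
        backtracks=backtracks,
        final_gradient_norm=float(np.sqrt((g * g).sum())),
        skipped_steps=skipped,
        admissibility=np.array(admiss),
    )


# ---------------------------------------------------------------- anchors

@dataclass
class AnchorWeightConfig:
    """How measurement quality maps to anchor weights.

    The base weight of every anchor of a vertex is its variance-explained
    fraction omega.  It is reduced by ``field_sign_factor`` when the field
    sign of the faces adjacent to the vertex (computed from the measured
    visual-field coordinates) mismatches the target area's field sign, and
    by a log-normal factor exp(-(ln(s_obs/s_model))^2 / (2 sigma_s^2)) for
    pRF-size mismatch against the model's linear size-vs-eccentricity
    function for the target area.  Either factor can be disabled.
    """

    threshold: float = 0.1
    field_sign_factor: float = 0.25
    use_field_sign: bool = True
    size_sigma: float = float(np.log(2.0))
    use_size: bool = True
    sigma_cap_factor: float = 20.0   # sigma <= cap_factor * epsilon


def _vertex_field_signs(fm: FlatMap, visual: np.ndarray) -> np.ndarray:
    """Per-vertex field sign: sign of the summed signs of adjacent faces."""
    fs = triangle_field_sign(fm.coordinates, visual, fm.faces)
    acc = np.zeros(fm.n_vertices)
    cnt = np.zeros(fm.n_vertices)
    ok = np.isfinite(fs)
    for k in range(3):
        np.add.at(acc, fm.faces[ok, k], fs[ok])
        np.add.at(cnt, fm.faces[ok, k], 1.0)
    out = np.sign(acc)
    out[cnt == 0] = np.nan
    return out


def build_anchors(data, model, sys: RegistrationSystem,
                  weight_config: AnchorWeightConfig | None = None) -> AnchorSet:
    """Construct the anchor set linking measured vertices to model positions.

    For every vertex with variance explained >= threshold and finite
    measurements, one anchor is created per modeled area, at the model
    point where that area represents the vertex's measured (theta, rho).
    Measurements an area does not represent (eccentricity beyond the
    model's range, polar angle outside the area's hemifield coverage) are
    skipped.  Each anchor's Gaussian width sigma is the distance from its
    point to the nearest other anchor point of the same vertex, capped at
    ``sigma_cap_factor`` times the reference mean edge length.

    ``data`` is a :class:`retmap.inference.RetinotopyData` aligned to the
    registration reference mesh.
    """
    wc = weight_config or AnchorWeightConfig()
    cap = wc.sigma_cap_factor * sys.epsilon
    n = sys.n_vertices
    theta = np.asarray(data.theta, dtype=float)
    rho = np.asarray(data.rho, dtype=float)
    size = np.asarray(data.size, dtype=float)
    omega = np.asarray(data.omega, dtype=float)
    ok = (np.isfinite(theta) & np.isfinite(rho) & np.isfinite(omega)
          & (omega >= wc.threshold))
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return AnchorSet.empty()

    # measured visual-field embedding (model hemifield convention)
    targets = visual_field_coords(theta[idx], rho[idx], "lh")

    if wc.use_field_sign:
        visual_all = visual_field_coords(
            np.where(np.isfinite(theta), theta, 0.0),
            np.where(np.isfinite(rho), rho, np.nan), "lh")
        vsign = _vertex_field_signs(sys.reference, visual_all)
    else:
        vsign = np.full(n, np.nan)

    a_vertex, a_point, a_weight, a_area = [], [], [], []
    for area in model.areas:
        # invert the model's field map restricted to this area: triangulate
        # the area's faces in visual-field space and locate the targets
        sel = model.face_areas == area
        if not sel.any():
            continue
        sub = FlatMap(model.visual_coords, model.mesh.faces[sel])
        fidx, bary = _locate_in(sub, targets)
        hit = fidx >= 0
        if not hit.any():
            continue
        pos = (model.mesh.coordinates[sub.faces[fidx[hit]]]
               * bary[hit][:, :, None]).sum(axis=1)
        verts = idx[hit]
        w = omega[verts].copy()
        if wc.use_field_sign:
            asign = model.area_field_sign(area)
            mism = np.isfinite(vsign[verts]) & (asign != 0) \
                & (vsign[verts] != 0) & (vsign[verts] != asign)
            w[mism] *= wc.field_sign_factor
        if wc.use_size:
            s_model = model.prf_size_at(area, rho[verts])
            s_obs = size[verts]
            good_s = np.isfinite(s_obs) & (s_obs > 0) & (s_model > 0)
            lr = np.zeros(len(verts))
            lr[good_s] = np.log(s_obs[good_s] / s_model[good_s])
            w = w * np.exp(-lr ** 2 / (2.0 * wc.size_sigma ** 2))
        a_vertex.append(verts)
        a_point.append(pos)
        a_weight.append(w)
        a_area.append(np.array([area] * len(verts), dtype=object))
    if not a_vertex:
        return AnchorSet.empty()
    vertex = np.concatenate(a_vertex)
    point = np.concatenate(a_point)
    weight = np.concatenate(a_weight)
    area = np.concatenate(a_area)
    # sigma: min distance to any other (non-coincident) anchor of the same
    # vertex, capped above at 20 epsilon and floored at epsilon/2 so wells
    # never become sharper than the mesh can resolve
    floor = 0.5 * sys.epsilon
    sigma = np.full(len(vertex), cap)
    order = np.argsort(vertex, kind="stable")
    sv, sp = vertex[order], point[order]
    starts = np.searchsorted(sv, np.unique(sv))
    bounds = np.append(starts, len(sv))
    for s, e in zip(bounds[:-1], bounds[1:]):
        if e - s < 2:
            continue
        pts = sp[s:e]
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
        d[d < 1e-9] = np.inf   # self and coincident anchor points
        sigma[order[s:e]] = np.clip(d.min(axis=1), floor, cap)
    return AnchorSet(vertex, point, sigma, weight, area)


def _locate_in(sub: FlatMap, targets: np.ndarray):
    from .mesh import locate_points
    return locate_points(sub, targets)
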