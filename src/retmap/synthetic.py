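"""Synthetic ground-truth models, warped subjects, and noisy pRF data.

The fixture model is a banded hemifield layout on a rectangular flat map:
eccentricity runs along x (fovea at x = 0, periphery at x = x_max, with the
standard exponential compression so the fovea is magnified), and polar angle
runs along y through a stack of mirror-image bands:

    hV4   y in [-4, -3]   upper quarterfield (theta 0..90)
    V3v   y in [-3, -2]   upper quarterfield
    V2v   y in [-2, -1]   upper quarterfield
    V1    y in [-1,  1]   full hemifield (theta 0..180)
    V2d   y in [ 1,  2]   lower quarterfield (theta 90..180)
    V3d   y in [ 2,  3]   lower quarterfield
    V3a   y in [ 3,  4]   lower quarterfield

Adjacent bands are mirror images, so face-wise field sign alternates, and
the outer ring (hV4, V3a) gives anchors from non-target areas realistic
pull.  The model fields are filled by the boundary-constrained minimization
in :mod:`retmap.model`, not written analytically, so the generator exercises
the same code path as a hand-labeled model.

Subjects are the model mesh warped by a smooth random displacement field
(sum of Gaussian bumps, rescaled until the warped mesh stays admissible);
the ground-truth retinotopy of a subject vertex is the model value at its
pre-warp position, so the subject's structure-function relationship differs
from the prior by exactly the warp.  Measurements add Gaussian polar-angle
noise, log-normal eccentricity noise, Gaussian pRF-size noise, Beta-
distributed variance explained, a vertical-meridian dropout band, and
coherent artifact blobs; averaging k simulated scans shrinks the noise like
1/sqrt(k).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import FlatMap, corner_angles
from .model import (BoundaryContour, BoundarySpec, RetinotopyModel,
                    build_model)
from .inference import RetinotopyData

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "make_synthetic_model",
    "warp_subject",
    "simulate_prf_data",
    "make_dataset",
]

@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic fixtures.

    The defaults are the simulation conditions used throughout the test
    suite: a subject warp of five mean edge lengths, single-scan polar
    angle noise of 20 deg, 10% multiplicative eccentricity noise, and a
    10 deg vertical-meridian dropout band.
    """

    resolution: float = 0.1            # model-mesh grid spacing (map units)
    x_max: float = 4.0                 # eccentricity-axis extent
    ecc_targets: tuple = (0.0, 3.0, 90.0)   # min / median / max deg
    warp_amplitude_edges: float = 5.0  # warp size in mean edge lengths
    warp_scale: float = 1.5            # Gaussian bump width (map units)
    warp_bumps: int = 6
    aperture_deg: float = 12.0         # stimulus aperture: no measurement
                                       # beyond this eccentricity
    sd_theta: float = 20.0             # deg, single scan
    sd_rho: float = 0.1                # log-sd of multiplicative ecc noise
    sd_size: float = 0.25              # deg, single scan
    dropout_halfwidth: float = 10.0    # deg of polar angle around meridians
    dropout_omega: float = 0.02        # omega level inside the dropout band
    blob_count: int = 3
    blob_radius_edges: float = 3.0     # artifact blob radius, in edge lengths
    blob_offset: float = 2.0           # coherent visual-field offset (deg)
    omega_alpha: float = 12.0          # Beta(alpha, beta) variance explained
    omega_beta: float = 3.0
    seed: int = 0


@dataclass
class SyntheticDataset:
    model: RetinotopyModel
    subject: FlatMap                   # warped subject map (native coords)
    true_positions: np.ndarray         # pre-warp (model-space) positions
    truth: RetinotopyData              # noiseless ground truth per vertex
    scans: list = field(default_factory=list)   # RetinotopyData per scan
    config: SyntheticConfig = None


def _grid_mesh(resolution: float, x_max: float) -> FlatMap:
    xs = np.arange(0.0, x_max + resolution / 2, resolution)
    ys = np.arange(-4.0, 4.0 + resolution / 2, resolution)
    nx, ny = len(xs), len(ys)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    coords = np.stack([xx.ravel(), yy.ravel()], axis=1)
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            faces.append((a, b, a + 1))
            faces.append((b, b + 1, a + 1))
    return FlatMap(coords, np.array(faces, dtype=np.intp))


def _boundary_spec(x_max: float) -> BoundarySpec:
    """Contours and polygons for the banded layout."""
    def hline(y, label, areas):
        return BoundaryContour(np.array([[0.0, y], [x_max, y]]), label, areas)

    contours = [
        hline(-4.0, "horizontal_meridian", ("hV4",)),
        hline(-3.0, "upper_vertical_meridian", ("hV4", "V3")),
        hline(-2.0, "horizontal_meridian", ("V3", "V2")),
        hline(-1.0, "upper_vertical_meridian", ("V2", "V1")),
        hline(1.0, "lower_vertical_meridian", ("V1", "V2")),
        hline(2.0, "horizontal_meridian", ("V2", "V3")),
        hline(3.0, "lower_vertical_meridian", ("V3", "V3a")),
        hline(4.0, "horizontal_meridian", ("V3a",)),
        BoundaryContour(np.array([[0.0, -4.0], [0.0, 4.0]]), "foveal",
                        ("hV4", "V3", "V2", "V1", "V3a")),
        BoundaryContour(np.array([[x_max, -4.0], [x_max, 4.0]]), "peripheral",
                        ("hV4", "V3", "V2", "V1", "V3a")),
    ]

    def rect(y0, y1):
        return np.array([[0.0, y0], [x_max, y0], [x_max, y1], [0.0, y1]])

    polygons = {
        "hV4": rect(-4.0, -3.0),
        "V3": np.array([[0.0, -3.0], [x_max, -3.0], [x_max, -2.0],
                        [0.0, -2.0], [0.0, 2.0], [x_max, 2.0],
                        [x_max, 3.0], [0.0, 3.0]]),
        "V2": np.array([[0.0, -2.0], [x_max, -2.0], [x_max, -1.0],
                        [0.0, -1.0], [0.0, 1.0], [x_max, 1.0],
                        [x_max, 2.0], [0.0, 2.0]]),
        "V1": rect(-1.0, 1.0),
        "V3a": rect(3.0, 4.0),
    }
    return BoundarySpec(contours=contours, area_polygons=polygons)


def make_synthetic_model(cfg: SyntheticConfig | None = None) -> RetinotopyModel:
    """Deterministic banded fixture model built through the model builder."""
    cfg = cfg or SyntheticConfig()
    mesh = _grid_mesh(cfg.resolution, cfg.x_max)
    spec = _boundary_spec(cfg.x_max)
    model = build_model(spec, mesh, ecc_targets=cfg.ecc_targets)
    return model


def warp_subject(mesh: FlatMap, amplitude: float, scale: float,
                 seed: int, n_bumps: int = 6,
                 max_tries: int = 40):
    """Smoothly warp a flat map while keeping every face admissible.

    The displacement field is a sum of ``n_bumps`` random Gaussian bumps of
    width ``scale``, tapered smoothly to zero toward the map perimeter (the
    perimeter of a cortical map projection is anatomically anchored, so
    structure-function differences live in its interior), normalized so the
    mean vertex displacement equals ``amplitude``, then shrunk geometrically
    until no corner angle leaves (0, pi) and every edge keeps a moderate
    strain.  Returns the warped FlatMap; ``amplitude = 0`` returns the
    mesh's own coordinates.
    """
    x = mesh.coordinates
    if amplitude == 0:
        return mesh.with_coordinates(x.copy())
    rng = np.random.default_rng(seed)
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    disp = np.zeros_like(x)
    margin_frac = 0.2
    for _ in range(n_bumps):
        center = lo + (margin_frac + (1 - 2 * margin_frac) * rng.random(2)) \
            * (hi - lo)
        direction = rng.normal(size=2)
        direction /= np.linalg.norm(direction)
        r2 = ((x - center) ** 2).sum(axis=1)
        disp += np.outer(np.exp(-r2 / (2 * scale ** 2)), direction)
    # smooth taper: 0 on the perimeter, 1 one ramp length inside; the ramp
    # is kept well below the map half-width so the interior is not starved
    dperim = np.min(np.sqrt(
        ((x[:, None, :] - x[mesh.perimeter][None, :, :]) ** 2).sum(axis=2)),
        axis=1)
    ramp = min(scale, 0.45 * dperim.max())
    taper = np.clip(dperim / ramp, 0.0, 1.0)
    taper = taper * taper * (3 - 2 * taper)   # smoothstep
    disp *= taper[:, None]
    mean_disp = np.sqrt((disp ** 2).sum(axis=1)).mean()
    if mean_disp == 0:
        raise RuntimeError("degenerate warp: taper removed all displacement")
    disp *= amplitude / mean_disp
    # soft-limit outlier magnitudes (direction preserved) so normalization
    # cannot concentrate the field into a few extreme vertices
    mag = np.sqrt((disp ** 2).sum(axis=1))
    lim = 2.2 * amplitude
    with np.errstate(invalid="ignore", divide="ignore"):
        fac = np.where(mag > 0, lim * np.tanh(mag / lim) / mag, 1.0)
    disp *= fac[:, None]
    disp *= amplitude / np.sqrt((disp ** 2).sum(axis=1)).mean()
    from .mesh import edge_lengths as _el
    r0 = _el(x, mesh.edges)
    for _ in range(max_tries):
        coords = x + disp
        ang = corner_angles(coords, mesh.angle_triples)
        r = _el(coords, mesh.edges)
        margin = 0.08
        if (np.all(ang > margin) and np.all(ang < np.pi - margin)
                and np.all(r > 0.5 * r0) and np.all(r < 1.7 * r0)):
            return mesh.with_coordinates(coords)
        disp *= 0.85
    raise RuntimeError("could not produce an admissible warp")


def simulate_prf_data(truth: RetinotopyData, cfg: SyntheticConfig,
                      positions: np.ndarray, mean_edge: float,
                      n_scans: int = 1, seed: int = 0) -> list:
    """Simulate ``n_scans`` noisy pRF measurement tables from ground truth.

    Polar angle gets additive Gaussian noise (clipped to the hemifield),
    eccentricity multiplicative log-normal noise, size additive Gaussian
    noise floored at 0.01 deg.  Variance explained is Beta-distributed,
    collapsed to ``dropout_omega`` within ``dropout_halfwidth`` of either
    vertical meridian and inside artifact blobs, where coherent offsets are
    also added.  ``positions`` (map coordinates) localize the blobs.
    """
    rng = np.random.default_rng(seed)
    out = []
    n = len(truth)
    near_meridian = ((truth.theta < cfg.dropout_halfwidth)
                     | (truth.theta > 180.0 - cfg.dropout_halfwidth))
    hw = cfg.dropout_halfwidth
    beyond_aperture = truth.rho > cfg.aperture_deg
    for _ in range(n_scans):
        theta = truth.theta + rng.normal(0, cfg.sd_theta, n)
        # measured maps systematically miss the vertical meridians: no
        # measurement ever reports a polar angle within the dropout band
        theta = np.clip(theta, hw, 180.0 - hw) if hw > 0 \
            else np.clip(theta, 0.0, 180.0)
        rho = truth.rho * np.exp(rng.normal(0, cfg.sd_rho, n))
        size = np.maximum(truth.size + rng.normal(0, cfg.sd_size, n), 0.01)
        omega = rng.beta(cfg.omega_alpha, cfg.omega_beta, n)
        omega = np.where(near_meridian | beyond_aperture,
                         cfg.dropout_omega * rng.random(n), omega)
        for _b in range(cfg.blob_count):
            center = positions[rng.integers(len(positions))]
            radius = cfg.blob_radius_edges * mean_edge
            inside = ((positions - center) ** 2).sum(axis=1) <= radius ** 2
            theta[inside] = np.clip(
                theta[inside] + rng.normal(0, 1) * 3 * cfg.sd_theta, 0, 180)
            rho[inside] = rho[inside] * np.exp(abs(rng.normal(0, 1))
                                               * cfg.blob_offset * 0.1)
        out.append(RetinotopyData(theta=theta, rho=rho, size=size,
                                  omega=omega,
                                  hemisphere=truth.hemisphere))
    return out


def average_scans(scans: list) -> RetinotopyData:
    """Average k scans as longer acquisition: noise shrinks like 1/sqrt(k).

    Angles are averaged through the visual-field embedding via their
    (theta, rho) values directly: theta and log-rho are averaged, omega by
    its mean, size by its mean.
    """
    theta = np.mean([s.theta for s in scans], axis=0)
    rho = np.exp(np.mean([np.log(np.maximum(s.rho, 1e-9)) for s in scans],
                         axis=0))
    size = np.mean([s.size for s in scans], axis=0)
    omega = np.mean([s.omega for s in scans], axis=0)
    return RetinotopyData(theta=theta, rho=rho, size=size, omega=omega,
                          hemisphere=scans[0].hemisphere)


def make_dataset(cfg: SyntheticConfig | None = None,
                 n_scans: int = 6,
                 model: RetinotopyModel | None = None) -> SyntheticDataset:
    """Compose model, warped subject and simulated scans into one dataset."""
    cfg = cfg or SyntheticConfig()
    if model is None:
        model = make_synthetic_model(cfg)
    mesh = model.mesh
    amplitude = cfg.warp_amplitude_edges * mesh.mean_edge_length
    subject = warp_subject(mesh, amplitude, cfg.warp_scale, seed=cfg.seed,
                           n_bumps=cfg.warp_bumps)
    # ground truth: the model's own per-vertex fields ride along with the
    # warp (vertex identity preserved), so the subject's true maps are the
    # model values at the pre-warp positions
    area = model.area
    size_true = np.full(len(model.theta), np.nan)
    for name in model.areas:
        sel = area == name
        size_true[sel] = model.prf_size_at(name, model.rho[sel])
    size_true = np.where(np.isfinite(size_true), size_true, 0.5)
    # even a noiseless experiment only measures within the aperture
    omega_true = (model.rho <= cfg.aperture_deg).astype(float)
    truth = RetinotopyData(theta=model.theta.copy(), rho=model.rho.copy(),
                           size=size_true, omega=omega_true,
                           hemisphere="lh")
    scans = simulate_prf_data(truth, cfg, subject.coordinates,
                              mesh.mean_edge_length, n_scans=n_scans,
                              seed=cfg.seed + 1)
    return SyntheticDataset(model=model, subject=subject,
                            true_positions=mesh.coordinates.copy(),
                            truth=truth, scans=scans, config=cfg)
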