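"""The user-facing pipeline: threshold and resample subject measurements,
register them to a retinotopy model, and read full-field predictions back
onto the subject's native vertices.

The subject's flattened map is assumed already expressed in the model's
(prior-aligned) coordinate frame; identity alignment is the default for
synthetic data.  Registration is run on a uniform resampling of the map;
the resulting displacement field is interpolated back to the native
vertices, and each native vertex is assigned the model values found at its
registered position.  Vertex identity is preserved throughout, so no
inverse registration is ever needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import FlatMap, barycentric_interpolate, uniform_resample
from .model import NO_AREA, RetinotopyModel, model_lookup
from .registration import (AnchorWeightConfig, MinimizerConfig,
                           RegistrationSystem, build_anchors, minimize)
from .visual import visual_field_angles, visual_field_coords

__all__ = [
    "RetinotopyData",
    "InferredMaps",
    "InsufficientDataError",
    "prepare_subject",
    "infer_maps",
    "fit_prf_size",
    "visual_field_coords",
    "visual_field_angles",
]

MIN_RETINOTOPIC_VERTICES = 10
PRF_SIZE_FLOOR = 0.01  # deg; inferred sizes never extrapolate below this


class InsufficientDataError(ValueError):
    pass


@dataclass
class RetinotopyData:
    """Per-vertex pRF measurements for one hemisphere.

    Vertices below the variance-explained threshold stay in place (indexing
    is never compacted); they are simply excluded from anchor generation.
    """

    theta: np.ndarray   # polar angle, deg in [0, 180]
    rho: np.ndarray     # eccentricity, deg >= 0
    size: np.ndarray    # pRF size, deg > 0 where present
    omega: np.ndarray   # variance explained fraction in [0, 1]
    hemisphere: str = "lh"
    vertex_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        self.size = np.asarray(self.size, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        n = len(self.theta)
        if not (len(self.rho) == len(self.size) == len(self.omega) == n):
            raise ValueError("measurement arrays must share one length")
        fin = np.isfinite(self.omega)
        if np.any((self.omega[fin] < 0) | (self.omega[fin] > 1)):
            raise ValueError("variance explained must lie in [0, 1]")
        if np.any(self.rho[np.isfinite(self.rho)] < 0):
            raise ValueError("eccentricity must be >= 0")
        if self.vertex_id is None:
            self.vertex_id = np.arange(n)
        else:
            self.vertex_id = np.asarray(self.vertex_id)

    def __len__(self) -> int:
        return len(self.theta)

    def above(self, threshold: float) -> np.ndarray:
        """Mask of usable vertices: finite fields, omega >= threshold."""
        return (np.isfinite(self.theta) & np.isfinite(self.rho)
                & np.isfinite(self.omega) & (self.omega >= threshold))


@dataclass
class InferredMaps:
    """Full-field per-vertex predictions on the subject's native vertices."""

    theta: np.ndarray
    rho: np.ndarray
    area: np.ndarray
    size: np.ndarray
    vertex_id: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.theta)


def prepare_subject(fm: FlatMap, data: RetinotopyData,
                    threshold: float = 0.1,
                    resolution: float | None = None):
    """Threshold and uniformly resample a subject's map and measurements.

    Angular fields are interpolated through the visual-field Cartesian
    embedding; variance explained is interpolated and re-thresholded on the
    resampled mesh.  The threshold is strict in the exclusion direction:
    omega >= threshold is retained.

    Returns (resampled FlatMap, resampled RetinotopyData).
    """
    if len(data) != fm.n_vertices:
        raise ValueError("data and flat map must share vertex indexing")
    usable = data.above(threshold)
    if usable.sum() < MIN_RETINOTOPIC_VERTICES:
        raise InsufficientDataError(
            f"only {int(usable.sum())} retinotopic vertices at or above "
            f"threshold {threshold}")
    if resolution is None:
        resolution = 1.5 * fm.mean_edge_length
    vis = visual_field_coords(np.where(usable, data.theta, 0.0),
                              np.where(usable, data.rho, np.nan), "lh")
    # zero out the interpolation weight of unusable vertices by NaN masking:
    # fields are interpolated as measured; faces touching NaN yield NaN,
    # which the resampled threshold then excludes.
    fields = {
        "_vx": vis[:, 0], "_vy": vis[:, 1],
        "_size": np.where(usable, data.size, np.nan),
        "_omega": np.where(np.isfinite(data.omega), data.omega, 0.0),
    }
    rs = uniform_resample(fm, resolution, fields)
    theta_r, rho_r = visual_field_angles(
        np.stack([rs.fields.pop("_vx"), rs.fields.pop("_vy")], axis=1), "lh")
    omega_r = rs.fields.pop("_omega")
    omega_r = np.clip(np.where(np.isfinite(omega_r), omega_r, 0.0), 0.0, 1.0)
    bad = ~(np.isfinite(theta_r) & np.isfinite(rho_r))
    omega_r = np.where(bad, 0.0, omega_r)
    rdata = RetinotopyData(theta=np.where(bad, np.nan, theta_r),
                           rho=np.where(bad, np.nan, rho_r),
                           size=rs.fields.pop("_size"),
                           omega=omega_r,
                           hemisphere=data.hemisphere)
    return rs, rdata


def infer_maps(fm: FlatMap, data: RetinotopyData | None,
               model: RetinotopyModel,
               reg_config: MinimizerConfig | None = None,
               weight_config: AnchorWeightConfig | None = None,
               resolution: float | None = None,
               fit_sizes: bool = True):
    """Bayesian retinotopic-map inference for one hemisphere.

    With measurements, the uniform resampling of the subject map is
    registered to the model and the displacement field is carried back to
    the native vertices; without any usable measurement the prior remains
    the prediction (the output is exactly the model lookup at the native
    coordinates).

    Returns (InferredMaps, RegistrationResult or None).
    """
    wc = weight_config or AnchorWeightConfig()
    native = fm.coordinates
    result = None
    n_anchors = 0
    registered_native = native
    if data is not None and data.above(wc.threshold).sum() > 0:
        rs, rdata = prepare_subject(fm, data, threshold=wc.threshold,
                                    resolution=resolution)
        sys = RegistrationSystem(rs)
        anchors = build_anchors(rdata, model, sys, wc)
        n_anchors = len(anchors)
        result = minimize(sys, anchors, reg_config)
        displacement = result.coordinates - sys.x0
        disp_native = barycentric_interpolate(rs, displacement, native)
        disp_native = np.where(np.isfinite(disp_native), disp_native, 0.0)
        registered_native = native + disp_native
    theta, rho, area = model_lookup(model, registered_native)
    size = np.full(len(theta), np.nan)
    inferred = InferredMaps(theta=theta, rho=rho, area=area, size=size,
                            vertex_id=np.arange(fm.n_vertices),
                            provenance={"n_anchors": n_anchors})
    if fit_sizes and data is not None:
        _fill_sizes(inferred, data, wc.threshold)
    return inferred, result


def _fill_sizes(inferred: InferredMaps, data: RetinotopyData,
                threshold: float) -> None:
    """Per-area linear size fits; areas with too little data stay NaN."""
    usable = data.above(threshold) & np.isfinite(data.size) & (data.size > 0)
    for area in np.unique(inferred.area[inferred.area != NO_AREA]):
        in_area = inferred.area == area
        train = in_area & usable & np.isfinite(inferred.rho)
        if train.sum() < 2 or np.unique(inferred.rho[train]).size < 2:
            continue
        m, b, _ = fit_prf_size(data.size[train], inferred.rho[train],
                               data.omega[train])
        inferred.size[in_area] = np.maximum(
            m * inferred.rho[in_area] + b, PRF_SIZE_FLOOR)


def fit_prf_size(s_obs, rho_inf, weights=None):
    """Weighted least-squares linear fit of pRF size on inferred eccentricity.

    Returns (slope, intercept, fitted sizes at ``rho_inf``, floored at
    ``PRF_SIZE_FLOOR``).
    """
    s = np.asarray(s_obs, dtype=float)
    r = np.asarray(rho_inf, dtype=float)
    w = np.ones_like(s) if weights is None else np.asarray(weights, float)
    ok = np.isfinite(s) & np.isfinite(r) & np.isfinite(w) & (w > 0)
    if ok.sum() < 2 or np.unique(r[ok]).size < 2:
        raise InsufficientDataError(
            "pRF-size fit needs >= 2 distinct eccentricities with weight")
    W = w[ok]
    X = np.stack([r[ok], np.ones(ok.sum())], axis=1)
    beta, *_ = np.linalg.lstsq(X * np.sqrt(W)[:, None],
                               s[ok] * np.sqrt(W), rcond=None)
    m, b = float(beta[0]), float(beta[1])
    return m, b, np.maximum(m * r + b, PRF_SIZE_FLOOR)
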