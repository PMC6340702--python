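"""Quantitative map-accuracy and deformation metrics.

Prediction error is measured in the visual field: the Euclidean distance
(deg) between the predicted and validation pRF centers, divided by the
validation eccentricity so that foveal and peripheral vertices contribute
comparably; squared errors are averaged with validation variance-explained
weights.  Deformation between alignment stages is summarized by the mean
3x3 inter-stage distance matrix, its exact planar embedding for three
points, and per-stage RMSD.  Cortical magnification is estimated with a
visual-field disk counter whose radius grows with eccentricity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .visual import visual_field_coords

__all__ = [
    "ErrorReport",
    "DeformationSummary",
    "MagnificationCurve",
    "scaled_error",
    "weighted_mse",
    "error_report",
    "cortical_magnification",
    "deformation_summary",
]


@dataclass
class ErrorReport:
    scaled_error: np.ndarray          # per-vertex, NaN where excluded
    weighted_mse: float
    median_abs_angle_error: float     # deg
    median_abs_ecc_error: float       # deg
    mean_abs_angle_error: float       # deg
    mean_abs_ecc_error: float         # deg
    n_excluded_zero_ecc: int
    band_mse: dict = field(default_factory=dict)


@dataclass
class DeformationSummary:
    mean_distances: np.ndarray        # 3x3: native, anatomical, retinotopic
    embedded_points: np.ndarray       # (3, 2) planar embedding
    anatomical_step: float            # ||A - N||
    retinotopic_step: float           # ||R - A||
    angle_deg: float                  # interior angle at A (NaN if degenerate)
    rmsd_anatomical: float
    rmsd_retinotopic: float


@dataclass
class MagnificationCurve:
    eccentricity: np.ndarray          # query points, deg
    magnification: np.ndarray         # mm^2 / deg^2, NaN where disk is empty


def scaled_error(pred_theta, pred_rho, valid_theta, valid_rho,
                 hemisphere: str = "lh") -> np.ndarray:
    """Eccentricity-scaled prediction error per vertex.

    Euclidean distance in the visual field between predicted and validation
    pRF centers, divided by the validation eccentricity.  Vertices with
    zero (or non-finite) validation eccentricity get NaN.
    """
    p = visual_field_coords(pred_theta, pred_rho, hemisphere)
    v = visual_field_coords(valid_theta, valid_rho, hemisphere)
    dist = np.sqrt(((p - v) ** 2).sum(axis=-1))
    rho_v = np.asarray(valid_rho, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        err = dist / rho_v
    err = np.where((rho_v > 0) & np.isfinite(err), err, np.nan)
    return err


def weighted_mse(errors, weights) -> float:
    """sum(w * e^2) / sum(w) over vertices with finite error and weight."""
    e = np.asarray(errors, dtype=float)
    w = np.asarray(weights, dtype=float)
    if len(e) != len(w):
        raise ValueError("errors and weights must share one length")
    ok = np.isfinite(e) & np.isfinite(w)
    wsum = w[ok].sum()
    if not wsum > 0:
        raise ValueError("all weights are zero (or nothing is finite)")
    return float((w[ok] * e[ok] ** 2).sum() / wsum)


def error_report(pred_theta, pred_rho, valid_theta, valid_rho,
                 weights=None, hemisphere: str = "lh",
                 bands=((0, 3), (3, 12))) -> ErrorReport:
    """Full accuracy report of a predicted map against validation data."""
    pt = np.asarray(pred_theta, float)
    pr = np.asarray(pred_rho, float)
    vt = np.asarray(valid_theta, float)
    vr = np.asarray(valid_rho, float)
    w = np.ones_like(vt) if weights is None else np.asarray(weights, float)
    err = scaled_error(pt, pr, vt, vr, hemisphere)
    ok = np.isfinite(err)
    d_theta = np.abs(pt - vt)
    d_rho = np.abs(pr - vr)
    fin = np.isfinite(d_theta) & np.isfinite(d_rho)
    band_mse = {}
    for lo, hi in bands:
        sel = ok & (vr >= lo) & (vr < hi)
        if sel.any() and w[sel].sum() > 0:
            band_mse[f"{lo}-{hi}"] = weighted_mse(err[sel], w[sel])
    return ErrorReport(
        scaled_error=err,
        weighted_mse=weighted_mse(err, w),
        median_abs_angle_error=float(np.median(d_theta[fin])),
        median_abs_ecc_error=float(np.median(d_rho[fin])),
        mean_abs_angle_error=float(np.mean(d_theta[fin])),
        mean_abs_ecc_error=float(np.mean(d_rho[fin])),
        n_excluded_zero_ecc=int((~ok).sum()),
        band_mse=band_mse,
    )


def cortical_magnification(prf_centers: np.ndarray,
                           vertex_areas_mm2: np.ndarray,
                           query_rho,
                           mask=None,
                           radius_fraction: float = 1.0 / 3.0,
                           query_theta_deg: float = 90.0,
                           hemisphere: str = "lh") -> MagnificationCurve:
    """Areal cortical magnification (mm^2 per deg^2) along a meridian.

    At each query eccentricity rho > 0 (on the horizontal meridian by
    default) the magnification is the summed vertex surface area of all
    pRF centers within a disk of radius alpha = rho * radius_fraction,
    divided by the disk area pi*alpha^2.  Empty disks give NaN.
    """
    centers = np.asarray(prf_centers, dtype=float)
    areas = np.asarray(vertex_areas_mm2, dtype=float)
    if mask is not None:
        centers = centers[mask]
        areas = areas[mask]
    q = np.atleast_1d(np.asarray(query_rho, dtype=float))
    out = np.full(len(q), np.nan)
    for i, rho in enumerate(q):
        if not rho > 0:
            continue
        alpha = rho * radius_fraction
        center = visual_field_coords(query_theta_deg, rho, hemisphere)
        d2 = ((centers - center) ** 2).sum(axis=1)
        inside = d2 <= alpha ** 2
        if inside.any():
            out[i] = areas[inside].sum() / (np.pi * alpha ** 2)
    return MagnificationCurve(eccentricity=q, magnification=out)


def deformation_summary(native, anatomical, retinotopic,
                        mask=None) -> DeformationSummary:
    """Summarize the two alignment deformations of a set of vertices.

    ``native``, ``anatomical`` and ``retinotopic`` are the per-vertex
    positions at the three alignment stages (same vertex ids, any common
    dimensionality).  Reports the mean 3x3 pairwise-distance matrix over
    the masked vertices, the exact planar embedding of those three mean
    points, the two step lengths with the interior angle at the anatomical
    stage, and the per-stage RMSD.
    """
    N = np.asarray(native, dtype=float)
    A = np.asarray(anatomical, dtype=float)
    R = np.asarray(retinotopic, dtype=float)
    if not (N.shape == A.shape == R.shape):
        raise ValueError("the three position sets must share a shape")
    if mask is not None:
        N, A, R = N[mask], A[mask], R[mask]
    if len(N) == 0:
        raise ValueError("empty vertex selection")

    def dist(u, v):
        return np.sqrt(((u - v) ** 2).sum(axis=-1))

    d_na = dist(N, A)
    d_ar = dist(A, R)
    d_nr = dist(N, R)
    m_na, m_ar, m_nr = (float(d.mean()) for d in (d_na, d_ar, d_nr))
    mean_mat = np.array([[0.0, m_na, m_nr],
                         [m_na, 0.0, m_ar],
                         [m_nr, m_ar, 0.0]])
    # exact planar embedding of three points from their pairwise distances:
    # A at the origin, N on the +x axis, R by the law of cosines
    if m_na > 0 and m_ar > 0:
        cosang = (m_na ** 2 + m_ar ** 2 - m_nr ** 2) / (2 * m_na * m_ar)
        cosang = float(np.clip(cosang, -1.0, 1.0))
        ang = float(np.degrees(np.arccos(cosang)))
        Rpt = m_ar * np.array([np.cos(np.radians(ang)),
                               np.sin(np.radians(ang))])
    else:
        ang = float("nan")
        Rpt = np.array([0.0, 0.0]) if m_ar == 0 else np.array([m_nr - m_na, 0.0])
    embedded = np.array([[m_na, 0.0], [0.0, 0.0], list(Rpt)])
    return DeformationSummary(
        mean_distances=mean_mat,
        embedded_points=embedded,
        anatomical_step=m_na,
        retinotopic_step=m_ar,
        angle_deg=ang,
        rmsd_anatomical=float(np.sqrt((d_na ** 2).mean())),
        rmsd_retinotopic=float(np.sqrt((d_ar ** 2).mean())),
    )
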