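"""Visual-field coordinate conventions.

Polar angle is measured in degrees from the upper vertical meridian (0°)
through the horizontal meridian (90°) to the lower vertical meridian (180°),
within one hemifield.  Eccentricity is degrees of visual angle from fixation.
The Cartesian embedding used for interpolation, field sign and distances is

    x = rho * sin(theta) * (+1 right visual field / -1 left),
    y = rho * cos(theta),

so a right-hemisphere cortical map (left visual field) carries sign -1.
"""

from __future__ import annotations

import numpy as np

__all__ = ["visual_field_coords", "visual_field_angles", "hemifield_sign"]


def hemifield_sign(hemisphere: str) -> float:
    """Sign of the visual-field x coordinate for a cortical hemisphere.

    The left hemisphere (``'lh'``) represents the right visual field (+1);
    the right hemisphere (``'rh'``) the left visual field (-1).
    """
    if hemisphere in ("lh", "left", "right_field"):
        return 1.0
    if hemisphere in ("rh", "right", "left_field"):
        return -1.0
    raise ValueError(f"unknown hemisphere {hemisphere!r}")


def visual_field_coords(theta_deg, rho_deg, hemisphere: str = "lh") -> np.ndarray:
    """Embed (polar angle, eccentricity) as Cartesian visual-field degrees."""
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    rho = np.asarray(rho_deg, dtype=float)
    s = hemifield_sign(hemisphere)
    return np.stack([rho * np.sin(th) * s, rho * np.cos(th)], axis=-1)


def visual_field_angles(xy, hemisphere: str = "lh"):
    """Inverse of :func:`visual_field_coords`: (theta deg, rho deg).

    At the origin (rho = 0) the polar angle is conventionally 0.
    """
    xy = np.asarray(xy, dtype=float)
    s = hemifield_sign(hemisphere)
    x = xy[..., 0] * s
    y = xy[..., 1]
    rho = np.hypot(x, y)
    theta = np.degrees(np.arctan2(x, y))
    theta = np.where(rho == 0, 0.0, theta)
    return theta, rho
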