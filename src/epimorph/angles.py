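"""Angle conventions and axial (mod-180) arithmetic.

Two kinds of angles appear in apical morphometrics:

* **axial** angles (cell orientation θ, principal stress direction ϑ₁) describe
  a line, not a vector, and are defined modulo 180°.  They are reported in the
  half-open interval (−90, 90], with 0° along the embryonic left–right (x) axis
  and 90° along the anterior–posterior (y) axis.
* **directional** angles (nucleus→Golgi polarity) describe a vector and live in
  (−180, 180].
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_axial",
    "wrap_directional",
    "axial_distance",
    "axial_mean",
    "axial_std",
    "ap_reference",
    "symmetrize_axial",
]


def wrap_axial(theta_deg):
    """Wrap angle(s) in degrees into the axial interval (−90, 90]."""
    t = np.asarray(theta_deg, dtype=float)
    out = (-t + 90.0) % 180.0  # maps 90 -> 0, -90+eps -> 180-eps
    out = 90.0 - out
    return out if out.ndim else float(out)


def wrap_directional(phi_deg):
    """Wrap angle(s) in degrees into the directional interval (−180, 180]."""
    p = np.asarray(phi_deg, dtype=float)
    out = (-p + 180.0) % 360.0
    out = 180.0 - out
    return out if out.ndim else float(out)


def axial_distance(a_deg, b_deg):
    """Smallest angle between two axes, in [0, 90] degrees."""
    d = (np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)) % 180.0
    d = np.minimum(d, 180.0 - d)
    return d if d.ndim else float(d)


def axial_mean(theta_deg):
    """Circular mean of axial angles (doubled-angle method), in (−90, 90]."""
    t = np.deg2rad(np.asarray(theta_deg, dtype=float)) * 2.0
    m = np.arctan2(np.mean(np.sin(t)), np.mean(np.cos(t))) / 2.0
    return wrap_axial(np.rad2deg(m))


def axial_std(theta_deg):
    """Circular standard deviation of axial angles, in degrees.

    Uses the doubled-angle resultant length R: std = sqrt(−2 ln R) / 2,
    converted back to degrees.  0 for perfectly aligned axes.
    """
    t = np.deg2rad(np.asarray(theta_deg, dtype=float)) * 2.0
    r = np.hypot(np.mean(np.sin(t)), np.mean(np.cos(t)))
    r = min(max(r, 1e-300), 1.0)
    return float(np.rad2deg(np.sqrt(-2.0 * np.log(r)) / 2.0))


def ap_reference(theta_deg):
    """Re-reference axial angles from the LR axis to the AP axis.

    Returns wrap_axial(θ − 90): 0 means "along the anterior–posterior axis".
    Cells aligned with the AP axis then carry values near 0 instead of
    straddling the ±90 axial wrap, which keeps regionally AP-oriented cells
    unimodal in plain-degree feature matrices.
    """
    return wrap_axial(np.asarray(theta_deg, dtype=float) - 90.0)


def symmetrize_axial(theta_deg, reference_deg):
    """Axial distance to a reference axis, in [0, 90] degrees.

    AP-symmetrization replaces θ by the axial distance to the AP axis
    (reference 90°) and ϑ₁ by |ϑ₁| (reference 0°); mirror-image left/right
    patterns then coincide.
    """
    return axial_distance(theta_deg, reference_deg)
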