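"""Per-specimen morphological indicators of the sperm head.

From the normalized EFD first harmonic: absolute major/minor axis
lengths (restoring the removed scale) and the aspect ratio d1 =
minor/major.  From the traced contour: the antero-posterior (AP) axis —
the longest chord between contour vertices (head length), the acute
angle theta between the AP chord and the first-harmonic major axis, and
the polygon (shoelace) head area.  Population dispersion is summarized
by the coefficient of variation in percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .efd import EFDCoefficients, efd_estimate, efd_normalize
from .geometry import as_contour, is_simple, signed_area

__all__ = [
    "HeadMeasurements",
    "ellipse_axes",
    "ap_axis_and_theta",
    "head_area",
    "coefficient_of_variation",
    "measure_head",
    "measurements_table",
]


@dataclass
class HeadMeasurements:
    """One specimen's morphological indicators (pixel units)."""

    specimen_id: str
    aspect_ratio: float
    major_px: float
    minor_px: float
    ap_length_px: float
    theta_deg: float
    area_px2: float


def ellipse_axes(coeffs: EFDCoefficients) -> tuple[float, float, float]:
    """Absolute first-harmonic axis lengths and their ratio.

    ``major = 2 * scale_px`` (the normalization removed the semi-major
    magnitude), ``minor = major * d1``.
    """
    if not coeffs.normalized:
        raise ValueError("ellipse_axes requires normalized coefficients")
    if not np.isfinite(coeffs.scale_px):
        raise ValueError("normalization scale record missing (scale_px is NaN)")
    major = 2.0 * coeffs.scale_px
    minor = major * coeffs.d1
    return major, minor, coeffs.d1


def ap_axis_and_theta(contour, coeffs: EFDCoefficients) -> tuple[float, float]:
    """Longest chord (AP axis) and its acute angle to the major axis.

    The AP axis is the maximum vertex-pair distance (attained on the
    convex hull); theta is reported in degrees in [0, 90).
    """
    c = as_contour(contour)
    pts = c[ConvexHull(c).vertices] if c.shape[0] > 12 else c
    D = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    if D.max() == 0:
        raise ValueError("degenerate contour: no positive vertex distance")
    i, j = np.unravel_index(int(np.argmax(D)), D.shape)
    ap = float(D[i, j])
    chord = pts[j] - pts[i]
    chord_angle = math.atan2(chord[1], chord[0])
    diff = abs(math.remainder(chord_angle - coeffs.rotation_rad, math.pi))
    if diff > 0.5 * math.pi:
        diff = math.pi - diff
    theta = math.degrees(diff)
    if theta >= 90.0:
        theta = 0.0
    return ap, theta


def head_area(contour) -> float:
    """Absolute shoelace area of the traced boundary polygon."""
    c = as_contour(contour)
    if not is_simple(c):
        raise ValueError("self-intersecting contour: area undefined")
    return abs(signed_area(c))


def coefficient_of_variation(values) -> float:
    """Sample CV in percent: 100 * SD(n-1) / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(f"CV needs >= 2 values, got {v.size}")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


def measure_head(specimen_id: str, contour,
                 coeffs: EFDCoefficients | None = None,
                 n_harmonics: int = 20) -> HeadMeasurements:
    """All indicators for one specimen (estimating EFDs if not supplied)."""
    if coeffs is None:
        coeffs = efd_normalize(efd_estimate(contour, n_harmonics,
                                            specimen_id=specimen_id))
    major, minor, ratio = ellipse_axes(coeffs)
    ap, theta = ap_axis_and_theta(contour, coeffs)
    return HeadMeasurements(specimen_id, ratio, major, minor, ap, theta,
                            head_area(contour))


def measurements_table(measurements: list[HeadMeasurements]) -> pd.DataFrame:
    """One row per specimen, columns as in :class:`HeadMeasurements`."""
    return pd.DataFrame([m.__dict__ for m in measurements]) \
        .set_index("specimen_id")
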