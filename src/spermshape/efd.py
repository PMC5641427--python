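"""Elliptic Fourier descriptors (EFD) of closed head contours.

A closed contour ``(x(t), y(t))`` parameterized by cumulative arc length
``t`` over total perimeter ``T`` is expanded as a truncated Fourier series

    X(t) = A0 + sum_n [ a_n cos(2 pi n t / T) + b_n sin(2 pi n t / T) ]
    Y(t) = C0 + sum_n [ c_n cos(2 pi n t / T) + d_n sin(2 pi n t / T) ]

for harmonics ``n = 1..N``.  Coefficients are estimated with the classical
closed-form line-integral estimator for piecewise-linear contours (the
chain-code/polygon formulation used throughout outline morphometrics).

Normalization removes the starting-point phase, the rotation, and the size
of the first-harmonic ellipse so that ``a1 = 1`` and ``b1 = c1 = 0``; the
remaining first-harmonic coefficient ``d1`` is the aspect ratio of that
ellipse (minor/major, in (0, 1] for counter-clockwise contours).  The
flattened free-parameter vector ``(d1, a2, b2, c2, d2, ..., dN)`` has
length ``4N - 3``.

Note that the first-harmonic ellipse is a Fourier construct, not a
geometric best fit: for an eccentric geometric ellipse traversed at
constant speed the series has energy in odd harmonics above 1, and the
first-harmonic axis ratio is slightly larger than the geometric axis
ratio (0.5869 vs 0.5 for a 2:1 ellipse; in the degenerate flat limit the
coordinate signal is a triangle wave whose first-harmonic amplitude is
8/pi^2 of the geometric semi-axis).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import as_contour

logger = logging.getLogger(__name__)

__all__ = [
    "EFDCoefficients",
    "efd_estimate",
    "efd_normalize",
    "efd_reconstruct",
    "flatten_coeffs",
    "unflatten_coeffs",
    "contour_aspect_ratio",
    "DEFAULT_N_HARMONICS",
]

#: Harmonic order used throughout the pipeline (4N-3 = 77 free parameters).
DEFAULT_N_HARMONICS = 20


@dataclass
class EFDCoefficients:
    """Harmonic coefficients plus the normalization record.

    ``coeffs`` is an ``(N, 4)`` array with columns ``a_n, b_n, c_n, d_n``.
    ``a0``/``c0`` are the centroid (DC) terms in pixels, kept from the raw
    estimate.  After normalization, ``scale_px`` is the removed
    first-harmonic semi-major magnitude, ``rotation_rad`` the removed
    spatial rotation and ``phase_rad`` the removed starting-point phase.
    """

    coeffs: np.ndarray
    a0: float = 0.0
    c0: float = 0.0
    scale_px: float = float("nan")
    rotation_rad: float = 0.0
    phase_rad: float = 0.0
    normalized: bool = False
    specimen_id: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.coeffs = np.atleast_2d(np.asarray(self.coeffs, dtype=float))
        if self.coeffs.shape[1] != 4:
            raise ValueError("coeffs must have 4 columns (a, b, c, d)")

    @property
    def n_harmonics(self) -> int:
        return self.coeffs.shape[0]

    @property
    def d1(self) -> float:
        """First-harmonic aspect ratio (only meaningful when normalized)."""
        return float(self.coeffs[0, 3])


def _segments(contour: np.ndarray):
    """Per-segment displacements and arc-length grid, closing the polygon.

    Zero-length segments (repeated vertices) are dropped so the estimator
    never divides by a zero step length.
    """
    closed = np.vstack([contour, contour[:1]])
    d = np.diff(closed, axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    keep = dt > 0
    d, dt = d[keep], dt[keep]
    start = closed[:-1][keep]
    if d.shape[0] < 3:
        raise ValueError("contour has zero perimeter or fewer than 3 distinct vertices")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    return start, d, dt, t


def efd_estimate(contour, n_harmonics: int = DEFAULT_N_HARMONICS,
                 specimen_id: str | None = None) -> EFDCoefficients:
    """Estimate raw (un-normalized) EFD coefficients of a closed polygon.

    Uses the closed-form integral of the Fourier projections over each
    linear segment, with ``t`` = cumulative arc length and ``T`` = perimeter.
    """
    c = as_contour(contour)
    if n_harmonics < 1:
        raise ValueError(f"n_harmonics must be >= 1, got {n_harmonics}")
    centered = c - c.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-12 * max(1.0, np.abs(centered).max())) < 2:
        raise ValueError("contour vertices are collinear")
    start, d, dt, t = _segments(c)
    T = t[-1]
    phi = 2.0 * np.pi * t / T                       # (S+1,)
    n = np.arange(1, n_harmonics + 1)[:, None]       # (N, 1)
    dcos = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])
    dsin = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    k = T / (2.0 * (n[:, 0] ** 2) * np.pi ** 2)
    vx, vy = d[:, 0] / dt, d[:, 1] / dt
    coeffs = np.empty((n_harmonics, 4))
    coeffs[:, 0] = k * (dcos @ vx)
    coeffs[:, 1] = k * (dsin @ vx)
    coeffs[:, 2] = k * (dcos @ vy)
    coeffs[:, 3] = k * (dsin @ vy)
    # DC terms: exact trapezoid of the piecewise-linear path
    mid = start + 0.5 * d
    a0 = float(np.sum(mid[:, 0] * dt) / T)
    c0 = float(np.sum(mid[:, 1] * dt) / T)
    return EFDCoefficients(coeffs, a0=a0, c0=c0, normalized=False,
                           specimen_id=specimen_id)


def _rot(angle: float) -> np.ndarray:
    ca, sa = math.cos(angle), math.sin(angle)
    return np.array([[ca, -sa], [sa, ca]])


def _apply_phase(M: np.ndarray, theta: float) -> np.ndarray:
    """Starting-point shift: harmonic n picks up a right rotation by n*theta."""
    out = np.empty_like(M)
    for i in range(M.shape[0]):
        out[i] = M[i] @ _rot((i + 1) * theta)
    return out


def efd_normalize(raw: EFDCoefficients) -> EFDCoefficients:
    """Normalize size, rotation and starting-point phase of the first harmonic.

    After normalization ``a1 = 1``, ``b1 = c1 = 0`` and ``d1`` in (0, 1] is
    the first-harmonic aspect ratio.  The removed scale, rotation and phase
    are recorded.  Of the residual 180-degree phase/rotation ambiguity
    (which flips the sign of every even harmonic), the variant making the
    dominant even-harmonic coefficient positive is chosen — anchoring the
    orientation to the shape's own asymmetry; symmetric shapes (all even
    harmonics ~0) tie, and the smaller starting-point phase wins.
    """
    if raw.normalized:
        return raw
    M = raw.coeffs.reshape(-1, 2, 2).copy()   # M[n-1] = [[a, b], [c, d]]
    a1, b1, c1, d1 = M[0].ravel()
    if not np.any(np.abs(M[0]) > 0):
        raise ValueError("zero first harmonic: cannot normalize")

    theta = 0.5 * math.atan2(2.0 * (a1 * b1 + c1 * d1),
                             a1 * a1 + c1 * c1 - b1 * b1 - d1 * d1)

    def axis1(th: float) -> float:
        return math.hypot(a1 * math.cos(th) + b1 * math.sin(th),
                          c1 * math.cos(th) + d1 * math.sin(th))

    # the closed form locates an extremum of the first-harmonic radius;
    # pick the branch where t = 0 sits on the semi-MAJOR axis
    if axis1(theta + 0.5 * math.pi) > axis1(theta):
        theta += 0.5 * math.pi
    theta = math.remainder(theta, 2.0 * math.pi)

    Mp = _apply_phase(M, theta)
    psi = math.atan2(Mp[0, 1, 0], Mp[0, 0, 0])
    Mn = _rot(-psi) @ Mp
    scale = Mn[0, 0, 0]
    if scale <= 0:
        raise ValueError("degenerate first harmonic: non-positive semi-major")
    Mn /= scale

    if Mn[0, 1, 1] < 0:
        # clockwise contour slipped through: mirror-correct so d1 > 0
        logger.warning("clockwise contour mirrored during EFD normalization "
                       "(specimen %s)", raw.specimen_id)
        Mn[:, 1, :] *= -1.0

    # residual (theta+pi, psi+pi) ambiguity flips the sign of every
    # even-harmonic coefficient; anchor the variant to the shape's own
    # asymmetry by requiring the dominant (largest-magnitude) even-harmonic
    # coefficient to be positive.  Near-symmetric outlines (all even
    # harmonics ~0, e.g. ellipses) tie; then the smaller phase wins.
    n_idx = np.arange(1, Mn.shape[0] + 1)
    even = (n_idx % 2) == 0
    ev = Mn[even].ravel()
    tie_tol = 1e-9
    dominant = float(ev[np.argmax(np.abs(ev))]) if ev.size else 0.0
    if dominant < -tie_tol or (abs(dominant) <= tie_tol
                               and not -0.5 * math.pi < theta <= 0.5 * math.pi):
        Mn[even] *= -1.0
        theta = math.remainder(theta + math.pi, 2.0 * math.pi)
        psi = math.remainder(psi + math.pi, 2.0 * math.pi)

    out = Mn.reshape(-1, 4)
    out[0, 0] = 1.0
    out[0, 1] = 0.0
    out[0, 2] = 0.0
    if not 0.0 < out[0, 3] <= 1.0 + 1e-9:
        raise ValueError(f"normalized d1 = {out[0, 3]!r} outside (0, 1]")
    out[0, 3] = min(out[0, 3], 1.0)
    return EFDCoefficients(out, a0=raw.a0, c0=raw.c0, scale_px=scale,
                           rotation_rad=psi, phase_rad=theta, normalized=True,
                           specimen_id=raw.specimen_id)


def efd_reconstruct(coeffs: EFDCoefficients, n_harmonics: int | None = None,
                    n_points: int = 256, include_dc: bool = False) -> np.ndarray:
    """Evaluate the truncated series at ``n_points`` uniform arc positions.

    ``include_dc`` adds the centroid terms back (meaningful for raw
    coefficients); normalized reconstructions live in the unit shape frame.
    """
    if n_harmonics is None:
        n_harmonics = coeffs.n_harmonics
    if n_harmonics < 1:
        raise ValueError(f"n_harmonics must be >= 1, got {n_harmonics}")
    if n_harmonics > coeffs.n_harmonics:
        raise ValueError(f"n_harmonics = {n_harmonics} exceeds available "
                         f"{coeffs.n_harmonics}")
    phi = 2.0 * np.pi * np.arange(n_points) / n_points
    n = np.arange(1, n_harmonics + 1)[:, None]
    cos_t, sin_t = np.cos(n * phi), np.sin(n * phi)
    C = coeffs.coeffs[:n_harmonics]
    x = C[:, 0] @ cos_t + C[:, 1] @ sin_t
    y = C[:, 2] @ cos_t + C[:, 3] @ sin_t
    if include_dc:
        x = x + coeffs.a0
        y = y + coeffs.c0
    return np.column_stack([x, y])


def flatten_coeffs(coeffs: EFDCoefficients) -> np.ndarray:
    """Free parameters of a normalized coefficient set, length ``4N - 3``.

    Order: ``d1`` first, then ``a_n, b_n, c_n, d_n`` for ``n = 2..N``.
    """
    if not coeffs.normalized:
        raise ValueError("flatten_coeffs requires normalized coefficients")
    return np.concatenate([[coeffs.coeffs[0, 3]], coeffs.coeffs[1:].ravel()])


def unflatten_coeffs(vector, scale_px: float = float("nan"),
                     specimen_id: str | None = None) -> EFDCoefficients:
    """Inverse of :func:`flatten_coeffs` (restores ``a1=1, b1=c1=0``)."""
    v = np.asarray(vector, dtype=float).ravel()
    if v.size < 1 or (v.size - 1) % 4 != 0:
        raise ValueError(f"flattened vector length must be 4N-3, got {v.size}")
    n_harmonics = (v.size + 3) // 4
    coeffs = np.zeros((n_harmonics, 4))
    coeffs[0] = [1.0, 0.0, 0.0, v[0]]
    coeffs[1:] = v[1:].reshape(-1, 4)
    return EFDCoefficients(coeffs, scale_px=scale_px, normalized=True,
                           specimen_id=specimen_id)


def contour_aspect_ratio(contour) -> float:
    """Convenience: first-harmonic aspect ratio d1 of a closed contour."""
    return efd_normalize(efd_estimate(contour, 1)).d1
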