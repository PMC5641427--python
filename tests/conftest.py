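"""Shared fixtures and independent numerical oracles."""

from __future__ import annotations

import numpy as np
import pytest

from spermshape import efd as efd_mod


def circle(n_points: int = 512, radius: float = 1.0) -> np.ndarray:
    t = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    return radius * np.column_stack([np.cos(t), np.sin(t)])


def ellipse(a: float, b: float, n_points: int = 512,
            angle: float = 0.0) -> np.ndarray:
    t = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    xy = np.column_stack([a * np.cos(t), b * np.sin(t)])
    c, s = np.cos(angle), np.sin(angle)
    return xy @ np.array([[c, s], [-s, c]])


def star_polygon(rng: np.random.Generator, n_vertices: int = 128) -> np.ndarray:
    """Random star-shaped (hence simple) polygon."""
    t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    n_lobes = int(rng.integers(2, 6))
    r = 1.0 + 0.35 * np.sin(n_lobes * t + rng.uniform(0, 2 * np.pi)) \
        + 0.15 * np.cos((n_lobes + 1) * t + rng.uniform(0, 2 * np.pi))
    return np.column_stack([r * np.cos(t), 0.8 * r * np.sin(t)])


def efd_quadrature_oracle(contour: np.ndarray, n_harmonics: int,
                          n_samples: int = 100_000) -> np.ndarray:
    """Fourier projection integrals by dense trapezoid quadrature.

    Resamples the closed polygon densely and uniformly in arc length,
    then integrates x(s)cos/sin(2 pi n s / T) directly — sharing no code
    path with the closed-form segment estimator it checks.
    """
    closed = np.vstack([contour, contour[:1]])
    seg = np.diff(closed, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    s_knots = np.concatenate([[0.0], np.cumsum(seglen)])
    T = s_knots[-1]
    s = np.linspace(0.0, T, n_samples)
    x = np.interp(s, s_knots, closed[:, 0])
    y = np.interp(s, s_knots, closed[:, 1])
    out = np.zeros((n_harmonics, 4))
    for n in range(1, n_harmonics + 1):
        w = 2.0 * np.pi * n * s / T
        cn, sn = np.cos(w), np.sin(w)
        out[n - 1, 0] = 2.0 / T * np.trapezoid(x * cn, s)
        out[n - 1, 1] = 2.0 / T * np.trapezoid(x * sn, s)
        out[n - 1, 2] = 2.0 / T * np.trapezoid(y * cn, s)
        out[n - 1, 3] = 2.0 / T * np.trapezoid(y * sn, s)
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def hooked_contour() -> np.ndarray:
    from spermshape.synthetic import make_template

    return make_template(0.5, 0.15, 256)


@pytest.fixture(scope="session")
def hooked_norm(hooked_contour):
    return efd_mod.efd_normalize(efd_mod.efd_estimate(hooked_contour, 20))
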