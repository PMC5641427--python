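"""Binarization and boundary tracing of nucleus-stained grayscale images.

Thresholding uses Otsu's discriminant criterion: an exhaustive scan of
all 256 grey levels for the threshold maximizing the between-class
variance of the histogram, with ties broken toward the lowest level.
Foreground is the bright class (``grey >= threshold``), matching
fluorescently stained nuclei on a dark background.

Object boundaries are traced with the Moore-neighbor algorithm on
8-connected components and emitted as Freeman chain codes in the
mathematical (y-up) frame: image row ``r`` maps to ``y = -r``, with the
origin at the top-left pixel center.  Emitted chains are
counter-clockwise (positive signed area after decoding).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .chaincode import ChainCode, DIR_VECTORS, chain_to_contour
from .geometry import signed_area

logger = logging.getLogger(__name__)

__all__ = ["BinaryMask", "otsu_threshold", "extract_contours", "DEFAULT_MIN_AREA"]

#: Components smaller than this (px^2) are treated as debris and dropped.
DEFAULT_MIN_AREA = 200


@dataclass
class BinaryMask:
    """Foreground mask plus the grey-level threshold that produced it."""

    mask: np.ndarray          # bool, (H, W)
    threshold_used: int

    @property
    def height(self) -> int:
        return self.mask.shape[0]

    @property
    def width(self) -> int:
        return self.mask.shape[1]


def otsu_threshold(image) -> tuple[int, BinaryMask]:
    """Discriminant-analysis (Otsu) binarization of an 8-bit image.

    Scans every candidate threshold ``T`` in 1..255, splitting the
    histogram into background (< T) and foreground (>= T), and returns
    the lowest ``T`` maximizing the between-class variance
    ``w0 * w1 * (mu0 - mu1)^2``.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    if img.dtype != np.uint8:
        if img.min() < 0 or img.max() > 255:
            raise ValueError("image values must lie in [0, 255]")
        img = img.astype(np.uint8)
    hist = np.bincount(img.ravel(), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: image has fewer than 2 grey levels")
    total = hist.sum()
    omega = np.cumsum(hist) / total            # P(grey <= t)
    mu = np.cumsum(hist * np.arange(256)) / total
    mu_total = mu[-1]
    best_t, best_var = 1, -1.0
    for t in range(1, 256):
        w0 = omega[t - 1]
        w1 = 1.0 - w0
        if w0 <= 0.0 or w1 <= 0.0:
            continue
        mu0 = mu[t - 1] / w0
        mu1 = (mu_total - mu[t - 1]) / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var + 1e-12:             # ties keep the lowest level
            best_var, best_t = var, t
    mask = img >= best_t
    return best_t, BinaryMask(mask=mask, threshold_used=best_t)


# Moore neighborhood in clockwise order (image coordinates, row down),
# starting from the western neighbor.
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
_MOORE_INDEX = {off: i for i, off in enumerate(_MOORE)}

# map image-frame steps (dr, dc) to Freeman codes in the y-up frame
_STEP_TO_CODE = {tuple((-v[1], v[0])): code for code, v in DIR_VECTORS.items()}
# DIR_VECTORS maps code -> (dx, dy); image step (dr, dc) = (-dy, dx)


def _trace_moore(component: np.ndarray) -> list[tuple[int, int]]:
    """Boundary pixels of a single component, Moore-neighbor traced.

    ``component`` is a padded boolean array.  Returns the closed pixel
    sequence (first pixel not repeated at the end).
    """
    rows, cols = np.nonzero(component)
    start = (int(rows[0]), int(cols[0]))       # raster order: topmost-leftmost
    p, b = start, (start[0], start[1] - 1)     # western backtrack is background
    seen: dict[tuple, int] = {}
    path: list[tuple[int, int]] = []
    while (p, b) not in seen:
        seen[(p, b)] = len(path)
        path.append(p)
        k0 = _MOORE_INDEX[(b[0] - p[0], b[1] - p[1])]
        nxt = None
        for j in range(1, 9):
            off_j = _MOORE[(k0 + j) % 8]
            cand = (p[0] + off_j[0], p[1] + off_j[1])
            if component[cand]:
                nxt = cand
                break
            b = cand
        if nxt is None:                         # isolated pixel
            return path
        p = nxt
    # the walk is deterministic, so the first repeated (pixel, backtrack)
    # state opens the boundary cycle; trim any lead-in
    return path[seen[(p, b)]:]


def extract_contours(mask: BinaryMask | np.ndarray,
                     min_area: float = DEFAULT_MIN_AREA,
                     id_prefix: str = "obj") -> list[ChainCode]:
    """Trace the outer boundary of each sufficiently large component.

    Components are 8-connected; those with pixel area below ``min_area``
    are dropped, as are degenerate boundaries (fewer than 3 boundary
    pixels).  Holes are ignored.  Chains are returned in raster order of
    the component seed pixel, CCW-oriented in the y-up frame.
    """
    m = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    labels, n_objects = ndimage.label(m, structure=np.ones((3, 3), dtype=int))
    chains: list[ChainCode] = []
    for lab in range(1, n_objects + 1):
        component = labels == lab
        area = int(component.sum())
        if area < min_area:
            continue
        padded = np.pad(component, 1)
        boundary = _trace_moore(padded)
        if len(boundary) < 3:
            logger.debug("dropping degenerate boundary of component %d", lab)
            continue
        # back to unpadded image coordinates, then to the y-up frame
        pix = [(r - 1, c - 1) for r, c in boundary]
        codes = []
        for (r0, c0), (r1, c1) in zip(pix, pix[1:] + pix[:1]):
            codes.append(_STEP_TO_CODE[(r1 - r0, c1 - c0)])
        chain = ChainCode(specimen_id=f"{id_prefix}{lab:03d}",
                          start=(pix[0][1], -pix[0][0]),
                          codes=np.asarray(codes, dtype=np.int8))
        contour = chain_to_contour(chain)       # enforces CCW
        if signed_area(contour) <= 0:
            logger.debug("dropping zero-area boundary of component %d", lab)
            continue
        chains.append(chain.oriented_ccw())
    return chains
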