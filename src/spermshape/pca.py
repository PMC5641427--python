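"""PCA over flattened EFD coefficient vectors.

Covariance PCA (divisor n-1) of the 4N-3 free coefficients, with
contribution rates, correlation factor loadings, shape reconstruction
along principal axes, and the two-pass abnormality filter: specimens
whose pass-1 PC1 score exceeds a fixed threshold (default 0.55) are
excluded as abnormal (rounder, hook-lacking outliers) and the model is
refit on the remainder.

Sign conventions: PC1 is oriented so the d1 entry of its eigenvector is
non-negative (higher PC1 = rounder / larger deviation from the thin
hooked norm, which puts abnormal specimens at high positive scores);
every other PC is oriented so its largest-magnitude entry is positive.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .efd import efd_reconstruct, unflatten_coeffs

logger = logging.getLogger(__name__)

__all__ = [
    "PCAModel",
    "AbnormalityFilterResult",
    "DEFAULT_ABNORMAL_THRESHOLD",
    "coefficient_names",
    "pca_fit",
    "factor_loadings",
    "biplot_arrow_lengths",
    "reconstruct_along_pc",
    "filter_abnormal",
]

#: Pass-1 PC1 score above which a specimen is classified abnormal.
DEFAULT_ABNORMAL_THRESHOLD = 0.55


def coefficient_names(n_params: int) -> list[str]:
    """Variable names in flattening order: d1, a2, b2, c2, d2, ..."""
    if (n_params - 1) % 4 != 0:
        raise ValueError(f"parameter count {n_params} is not of the form 4N-3")
    n_harmonics = (n_params + 3) // 4
    return ["d1"] + [f"{c}{n}" for n in range(2, n_harmonics + 1) for c in "abcd"]


@dataclass
class PCAModel:
    """Eigen-decomposition of the sample covariance of coefficient vectors."""

    mean_vector: np.ndarray
    eigenvectors: np.ndarray      # columns = PCs, orthonormal
    eigenvalues: np.ndarray       # descending, >= 0
    contribution_rates: np.ndarray
    n_specimens: int

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size

    def transform(self, matrix) -> np.ndarray:
        X = np.asarray(matrix, dtype=float)
        return (X - self.mean_vector) @ self.eigenvectors

    def to_json(self, path) -> None:
        payload = {
            "mean_vector": self.mean_vector.tolist(),
            "eigenvectors": self.eigenvectors.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "contribution_rates": self.contribution_rates.tolist(),
            "n_specimens": self.n_specimens,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "PCAModel":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["mean_vector"]), np.asarray(d["eigenvectors"]),
                   np.asarray(d["eigenvalues"]),
                   np.asarray(d["contribution_rates"]), int(d["n_specimens"]))


def _score_frame(scores: np.ndarray, ids) -> pd.DataFrame:
    cols = [f"PC{k + 1}" for k in range(scores.shape[1])]
    index = pd.Index(ids if ids is not None
                     else [f"s{i:04d}" for i in range(scores.shape[0])],
                     name="specimen_id")
    return pd.DataFrame(scores, index=index, columns=cols)


def pca_fit(matrix, ids=None, d1_index: int = 0) -> tuple[PCAModel, pd.DataFrame]:
    """Covariance PCA of a specimens x parameters matrix.

    Returns the model and the score table (centered data projected on the
    eigenvectors).  Rank-deficient covariance is allowed (zero
    eigenvalues are retained); rows containing NaN raise an error naming
    the offending specimens.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("pca_fit needs a 2-D matrix with >= 3 specimens")
    bad = np.nonzero(~np.isfinite(X).all(axis=1))[0]
    if bad.size:
        labels = [ids[i] if ids is not None else f"s{i:04d}" for i in bad]
        raise ValueError(f"non-finite coefficients for specimens: {labels}")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / (X.shape[0] - 1)
    eigenvalues, eigenvectors = np.linalg.eigh(cov)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = np.clip(eigenvalues[order], 0.0, None)
    eigenvectors = eigenvectors[:, order]
    # sign conventions
    if eigenvectors[d1_index, 0] < 0:
        eigenvectors[:, 0] *= -1.0
    for k in range(1, eigenvectors.shape[1]):
        j = int(np.argmax(np.abs(eigenvectors[:, k])))
        if eigenvectors[j, k] < 0:
            eigenvectors[:, k] *= -1.0
    total = eigenvalues.sum()
    rates = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    model = PCAModel(mean, eigenvectors, eigenvalues, rates, X.shape[0])
    return model, _score_frame(Xc @ eigenvectors, ids)


def factor_loadings(model: PCAModel, matrix, ids=None) -> pd.DataFrame:
    """Correlation loadings: loading(j, k) = corr(variable j, score k).

    Computed as ``e_jk * sqrt(lambda_k) / s_j``; zero-variance variables
    get loading 0 with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    s = X.std(axis=0, ddof=1)
    zero = s <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance variables have "
                      "undefined loadings (set to 0)", stacklevel=2)
    safe = np.where(zero, 1.0, s)
    L = model.eigenvectors * np.sqrt(model.eigenvalues)[None, :] / safe[:, None]
    L[zero, :] = 0.0
    L = np.clip(L, -1.0, 1.0)
    names = coefficient_names(X.shape[1]) if (X.shape[1] - 1) % 4 == 0 \
        else [f"v{j}" for j in range(X.shape[1])]
    return pd.DataFrame(L, index=pd.Index(names, name="variable"),
                        columns=[f"PC{k + 1}" for k in range(L.shape[1])])


def biplot_arrow_lengths(loadings: pd.DataFrame,
                         display_threshold: float = 0.1) -> pd.DataFrame:
    """Biplot arrow lengths sqrt(l_PC1^2 + l_PC2^2), flagged for display."""
    length = np.hypot(loadings["PC1"], loadings["PC2"])
    return pd.DataFrame({"arrow_length": length,
                         "display": length > display_threshold})


def reconstruct_along_pc(model: PCAModel, pc: int, k: float,
                         n_points: int = 256) -> np.ndarray:
    """Shape at ``mean + k * sqrt(lambda_pc) * eigenvector_pc``.

    ``pc`` is 1-based; ``|k| <= 3``.  Raises if the displaced coefficient
    vector leaves the valid shape space (d1 <= 0).
    """
    if not 1 <= pc <= model.n_components:
        raise ValueError(f"pc must be in 1..{model.n_components}, got {pc}")
    if abs(k) > 3:
        raise ValueError(f"|k| must be <= 3 SD, got {k}")
    vec = model.mean_vector + k * np.sqrt(model.eigenvalues[pc - 1]) \
        * model.eigenvectors[:, pc - 1]
    if vec[0] <= 0:
        raise ValueError(f"reconstruction at PC{pc}, k={k} leaves the valid "
                         f"shape space (d1 = {vec[0]:.4f})")
    return efd_reconstruct(unflatten_coeffs(vec), n_points=n_points)


@dataclass
class AbnormalityFilterResult:
    """Outcome of the two-pass abnormality filter."""

    normal_matrix: np.ndarray
    normal_ids: list
    abnormal_ids: list
    pass1_model: PCAModel
    pass1_scores: pd.DataFrame
    pass2_model: PCAModel
    pass2_scores: pd.DataFrame
    threshold: float


def filter_abnormal(matrix, ids=None,
                    threshold: float = DEFAULT_ABNORMAL_THRESHOLD
                    ) -> AbnormalityFilterResult:
    """Exclude specimens with pass-1 PC1 score above ``threshold``, refit.

    Pass 1 fits PCA on all specimens (abnormal included, anchoring the
    score scale); pass 2 refits on the retained normal set.  Raises if
    no specimen survives.
    """
    X = np.asarray(matrix, dtype=float)
    if ids is None:
        ids = [f"s{i:04d}" for i in range(X.shape[0])]
    model1, scores1 = pca_fit(X, ids)
    keep = scores1["PC1"].to_numpy() <= threshold
    if not keep.any():
        raise ValueError(f"all specimens exceed the PC1 threshold {threshold}")
    abnormal_ids = [sid for sid, k in zip(ids, keep) if not k]
    normal_ids = [sid for sid, k in zip(ids, keep) if k]
    if keep.sum() < 3:
        raise ValueError("fewer than 3 specimens remain after the "
                         "abnormality filter")
    model2, scores2 = pca_fit(X[keep], normal_ids)
    logger.info("abnormality filter: %d/%d specimens excluded at "
                "PC1 > %.2f", len(abnormal_ids), len(ids), threshold)
    return AbnormalityFilterResult(X[keep], normal_ids, abnormal_ids,
                                   model1, scores1, model2, scores2, threshold)
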