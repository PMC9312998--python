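"""Shape-space and form-space principal component analysis.

Shape space: PCA of the flattened Procrustes coordinates.  Form space
(shape plus size): the same matrix augmented by one unweighted column of
ln(centroid size), so the leading axis typically absorbs size variation.

Axis sign convention: each component is oriented so that its largest-
magnitude loading is positive; form-space PC1 is additionally oriented so
the lnCS loading is positive, which on size-dimorphic samples puts the
larger sex at positive PC1 scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .procrustes import ProcrustesResult


@dataclass
class PCAModel:
    space: str  # "shape" | "form"
    mean_vector: np.ndarray  # (D,), D = 3K (+1 for form)
    axes: np.ndarray  # (m, D) orthonormal rows
    eigenvalues: np.ndarray  # (m,) non-increasing
    scores: np.ndarray  # (N, m)
    variance_fraction: np.ndarray  # (m,), sums to 1

    @property
    def n_components(self) -> int:
        return self.axes.shape[0]

    @property
    def n_landmarks(self) -> int:
        d = self.mean_vector.size - (1 if self.space == "form" else 0)
        return d // 3

    def cumulative_variance(self, k: int) -> float:
        return float(self.variance_fraction[:k].sum())

    def project(self, vectors: np.ndarray) -> np.ndarray:
        """Scores of new flattened observations (rows) in this space."""
        return (np.atleast_2d(vectors) - self.mean_vector) @ self.axes.T


def _pca_from_matrix(data: np.ndarray, space: str) -> PCAModel:
    n = data.shape[0]
    if n < 3:
        raise ValueError("PCA needs at least 3 observations")
    mean = data.mean(axis=0)
    centered = data - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    m = min(n - 1, data.shape[1])
    u, s, vt = u[:, :m], s[:m], vt[:m]
    eigenvalues = s**2 / (n - 1)
    scores = u * s
    axes = vt

    # sign convention: largest-|loading| entry positive per axis
    for j in range(m):
        pivot = np.argmax(np.abs(axes[j]))
        if axes[j, pivot] < 0:
            axes[j] = -axes[j]
            scores[:, j] = -scores[:, j]
    if space == "form" and m > 0 and axes[0, -1] < 0:
        axes[0] = -axes[0]
        scores[:, 0] = -scores[:, 0]

    total = eigenvalues.sum()
    return PCAModel(
        space=space,
        mean_vector=mean,
        axes=axes,
        eigenvalues=eigenvalues,
        scores=scores,
        variance_fraction=eigenvalues / total if total > 0 else eigenvalues,
    )


def shape_pca(result: ProcrustesResult) -> PCAModel:
    """PCA of the flattened aligned shape coordinates."""
    n = result.aligned.shape[0]
    return _pca_from_matrix(result.aligned.reshape(n, -1), "shape")


def form_pca(result: ProcrustesResult) -> PCAModel:
    """PCA of [flattened shape coordinates | ln centroid size].

    The lnCS column enters unweighted; the mean vector's trailing entry is
    the mean lnCS.
    """
    n = result.aligned.shape[0]
    if np.any(result.centroid_sizes <= 0):
        raise ValueError("centroid sizes must be positive for form space")
    data = np.hstack(
        [result.aligned.reshape(n, -1), np.log(result.centroid_sizes)[:, None]]
    )
    return _pca_from_matrix(data, "form")


def reconstruct_along_pc(
    model: PCAModel, pc_index: int, score: float
) -> tuple[np.ndarray, float | None]:
    """Configuration at ``mean + score * axis`` along one component.

    Returns (K x 3 coordinates, lnCS) — lnCS is None for shape space.
    """
    if not 0 <= pc_index < model.n_components:
        raise IndexError(f"pc_index {pc_index} out of range")
    vector = model.mean_vector + score * model.axes[pc_index]
    if model.space == "form":
        return vector[:-1].reshape(-1, 3), float(vector[-1])
    return vector.reshape(-1, 3), None


def reconstruct_from_scores(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    """Flattened observation at a full score vector (inverse transform)."""
    return model.mean_vector + np.asarray(scores) @ model.axes


def group_mean_shape(result: ProcrustesResult, subset: np.ndarray) -> np.ndarray:
    """Mean aligned shape of a subset (boolean mask or index array),
    re-standardized to zero centroid and unit centroid size."""
    subset = np.asarray(subset)
    coords = result.aligned[subset]
    if coords.size == 0:
        raise ValueError("empty subset")
    mean = coords.mean(axis=0)
    mean = mean - mean.mean(axis=0)
    return mean / np.sqrt(np.sum(mean**2))
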