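"""Generalized Procrustes Analysis.

Partial Procrustes superimposition: every configuration is centred, scaled
to unit centroid size, and rotated (no reflections — all specimens are
left-side bones) onto a recursively updated consensus.  Centroid sizes are
recorded in the original units (mm) before scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

MAX_ITERATIONS = 100
CONVERGENCE_TOL = 1e-10


@dataclass
class ProcrustesResult:
    aligned: np.ndarray  # (N, K, 3), unit centroid size, centred
    consensus: np.ndarray  # (K, 3), unit centroid size
    centroid_sizes: np.ndarray  # (N,), mm
    iterations: int
    converged: bool


def centroid_size(coords: np.ndarray) -> float:
    """Square root of the summed squared distances of all landmarks from
    their centroid."""
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered**2)))
    if cs <= 0:
        raise ValueError("degenerate configuration: zero centroid size")
    return cs


def _standardize(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    return centered / np.sqrt(np.sum(centered**2))


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimizing ||source @ R - target||_F.

    If the unconstrained optimum is a reflection, the smallest singular
    direction is sign-flipped (standard constrained orthogonal Procrustes).
    """
    h = source.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    if d < 0:
        logger.debug("reflection optimum encountered; constraining to rotation")
    flip = np.diag([1.0, 1.0, d])
    return u @ flip @ vt


def _orient_to_principal_axes(result: "ProcrustesResult") -> None:
    """Rotate consensus (and all aligned shapes) so its principal axes lie
    along +x,+y,+z with positive third moment, making output orientation
    reproducible across runs."""
    cons = result.consensus
    _, _, vt = np.linalg.svd(cons - cons.mean(axis=0), full_matrices=False)
    rot = vt.T  # columns: principal axes
    projected = (cons - cons.mean(axis=0)) @ rot
    skews = (projected**3).sum(axis=0)
    signs = np.where(skews >= 0, 1.0, -1.0)
    if np.prod(signs) * np.linalg.det(rot) < 0:
        # keep det +1: give up the sign preference on the axis of smallest skew
        signs[np.argmin(np.abs(skews))] *= -1
    rot = rot @ np.diag(signs)
    result.consensus = cons @ rot
    result.aligned = result.aligned @ rot


def gpa_align(configs: list[np.ndarray] | np.ndarray) -> ProcrustesResult:
    """Generalized Procrustes alignment of N configurations of K landmarks.

    Iterates rotate-to-consensus / update-consensus until the consensus
    moves less than 1e-10 or 100 iterations.  The result is invariant (up to
    a global orientation fixed by the consensus principal axes) to arbitrary
    rigid motion and scaling of the inputs.
    """
    arrays = [np.asarray(c, dtype=float) for c in configs]
    if len(arrays) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    k = arrays[0].shape
    if any(a.shape != k for a in arrays):
        raise ValueError("configurations differ in landmark count")

    sizes = np.array([centroid_size(a) for a in arrays])
    shapes = np.stack([_standardize(a) for a in arrays])

    consensus = shapes[0].copy()
    iterations = 0
    converged = False
    for iterations in range(1, MAX_ITERATIONS + 1):
        for i in range(shapes.shape[0]):
            shapes[i] = shapes[i] @ optimal_rotation(shapes[i], consensus)
        new_consensus = _standardize(shapes.mean(axis=0))
        change = np.sqrt(np.sum((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if change < CONVERGENCE_TOL:
            converged = True
            break
    if not converged:
        logger.warning("GPA did not converge in %d iterations", MAX_ITERATIONS)

    result = ProcrustesResult(
        aligned=shapes,
        consensus=consensus,
        centroid_sizes=sizes,
        iterations=iterations,
        converged=converged,
    )
    _orient_to_principal_axes(result)
    return result


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations.

    Both are standardized (centred, unit centroid size); b is optimally
    rotated onto a; the distance is the root summed squared coordinate
    difference.  Symmetric.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("configurations differ in shape")
    sa, sb = _standardize(a), _standardize(b)
    sb = sb @ optimal_rotation(sb, sa)
    return float(np.sqrt(np.sum((sa - sb) ** 2)))
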