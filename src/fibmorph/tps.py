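"""3D thin-plate spline interpolation and bending energy.

The spline interpolating ``source -> target`` uses the radial kernel
U(r) = -r (the sign that makes the bending-energy quadratic form positive
semidefinite in 3D) plus an affine term.  The bending-energy matrix of a
reference configuration is the upper-left K x K block of the inverse of the
bordered kernel matrix

    L = [[U(|x_i - x_j|),  1  x_i],
         [[1 x_j]^T,        0    ]]

and the bending energy of a deformation is the sum over coordinate axes of
the quadratic form v^T B v.  B annihilates affine functions of the
reference, so affine deformations (including rigid motions and scalings)
have zero energy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

_ENERGY_CLAMP = 1e-12  # energies below this are numerical zero


class DegenerateConfigurationError(ValueError):
    """Source points coincident or coplanar: TPS system is singular."""


@dataclass
class TPSSpline:
    """f(x) = affine part + sum_i w_i U(|x - c_i|), columns are x,y,z."""

    control_points: np.ndarray  # (K, 3)
    weights: np.ndarray  # (K, 3) non-affine coefficients
    affine: np.ndarray  # (4, 3): row 0 constant, rows 1..3 linear


@dataclass
class BendingEnergyMatrix:
    reference: np.ndarray  # (K, 3)
    matrix: np.ndarray  # (K, K) symmetric PSD


def _kernel(distances: np.ndarray) -> np.ndarray:
    return -distances


def _check_nondegenerate(source: np.ndarray) -> None:
    k = source.shape[0]
    if k < 4:
        raise DegenerateConfigurationError("TPS needs at least 4 control points")
    centered = source - source.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 3:
        raise DegenerateConfigurationError(
            "control points are coplanar; affine part underdetermined"
        )
    d = cdist(source, source)
    np.fill_diagonal(d, np.inf)
    if d.min() <= 0:
        raise DegenerateConfigurationError("coincident control points")


def _bordered_matrix(source: np.ndarray, regularization: float = 0.0) -> np.ndarray:
    k = source.shape[0]
    km = _kernel(cdist(source, source))
    if regularization:
        km = km + regularization * np.eye(k)
    p = np.hstack([np.ones((k, 1)), source])
    L = np.zeros((k + 4, k + 4))
    L[:k, :k] = km
    L[:k, k:] = p
    L[k:, :k] = p.T
    return L


def fit_tps(
    source: np.ndarray, target: np.ndarray, regularization: float = 0.0
) -> TPSSpline:
    """Fit the 3D TPS mapping source control points onto target points.

    With ``regularization`` 0 the spline interpolates exactly; positive
    values trade exactness for smoothness (standard ridge on the kernel
    block).
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape or source.ndim != 2 or source.shape[1] != 3:
        raise ValueError("source and target must both be K x 3")
    if regularization < 0:
        raise ValueError("regularization must be non-negative")
    _check_nondegenerate(source)
    k = source.shape[0]
    L = _bordered_matrix(source, regularization)
    rhs = np.zeros((k + 4, 3))
    rhs[:k] = target
    try:
        solution = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:
        raise DegenerateConfigurationError(f"singular TPS system: {exc}") from exc
    return TPSSpline(
        control_points=source.copy(), weights=solution[:k], affine=solution[k:]
    )


def evaluate_tps(spline: TPSSpline, points: np.ndarray) -> np.ndarray:
    """Evaluate the spline at an M x 3 array of points."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[1] != 3:
        raise ValueError("points must be M x 3")
    km = _kernel(cdist(points, spline.control_points))
    p = np.hstack([np.ones((points.shape[0], 1)), points])
    return km @ spline.weights + p @ spline.affine


def bending_energy_matrix(reference: np.ndarray) -> BendingEnergyMatrix:
    """Bending-energy matrix of a reference configuration.

    Upper-left K x K block of the inverse bordered kernel matrix; symmetric
    positive semidefinite, annihilating [1 | x | y | z].  On numerical
    singularity a small ridge (1e-10 * trace magnitude) is added and logged.
    """
    reference = np.asarray(reference, dtype=float)
    _check_nondegenerate(reference)
    k = reference.shape[0]
    L = _bordered_matrix(reference)
    try:
        inv = np.linalg.inv(L)
    except np.linalg.LinAlgError:
        ridge = 1e-10 * np.abs(np.trace(L[:k, :k]))
        logger.warning("bending-energy system singular; adding ridge %.3e", ridge)
        inv = np.linalg.inv(L + ridge * np.eye(k + 4))
    b = inv[:k, :k]
    b = (b + b.T) / 2.0
    return BendingEnergyMatrix(reference=reference.copy(), matrix=b)


def bending_energy(
    reference: np.ndarray,
    deformed: np.ndarray,
    bem: BendingEnergyMatrix | None = None,
) -> float:
    """TPS bending energy of the map taking ``reference`` onto ``deformed``.

    Zero iff the deformation is affine (translations, rotations, scalings
    included).  ``bem`` may pass a precomputed matrix for the reference.
    """
    reference = np.asarray(reference, dtype=float)
    deformed = np.asarray(deformed, dtype=float)
    if reference.shape != deformed.shape:
        raise ValueError("reference and deformed must have matching shapes")
    if bem is None:
        bem = bending_energy_matrix(reference)
    energy = float(np.einsum("kd,kl,ld->", deformed, bem.matrix, deformed))
    if energy < _ENERGY_CLAMP:
        energy = 0.0
    return energy
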