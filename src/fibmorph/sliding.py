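"""Sliding-semilandmark relaxation.

Curve and surface semilandmarks carry no pointwise homology; they are made
geometrically comparable by letting them slide along locally estimated
tangent directions so as to minimize the thin-plate-spline bending energy
between each specimen and a reference.  Two uses:

* relaxation of one configuration against a fixed reference (template
  application), and
* sample-wide relaxation against recursive updates of the Procrustes
  consensus (``slide_sample``).

Tangents are estimated from coordinates alone (the pipeline receives
landmarks, not meshes): central differences along the ordered curve for
curve points, the two leading principal directions of the k nearest
within-patch neighbours for surface points.  There is no underlying surface
to reproject onto, so per-pass displacements are capped to prevent
fly-away.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import LandmarkConfiguration, Sample, TemplateDefinition
from .procrustes import centroid_size, gpa_align, optimal_rotation
from .tps import BendingEnergyMatrix, bending_energy, bending_energy_matrix

logger = logging.getLogger(__name__)

DEFAULT_OUTER_ITERATIONS = 3
DEFAULT_K_NEIGHBORS = 8


@dataclass
class TangentFrame:
    """Unit tangent directions per semilandmark label.

    Curve points carry one tangent, surface points two orthonormal tangents;
    fixed landmarks carry none.
    """

    tangents: dict[str, np.ndarray] = field(default_factory=dict)

    def directions(self, label: str) -> np.ndarray | None:
        return self.tangents.get(label)


@dataclass
class SlidingReport:
    iterations_run: int
    energy_per_iteration: list[float]
    max_displacement_mm: float


def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length tangent")
    return v / n


def estimate_tangent_frames(
    config: LandmarkConfiguration,
    template: TemplateDefinition,
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
) -> TangentFrame:
    """Estimate sliding directions for every semilandmark of a configuration.

    Curve tangents: central difference of the neighbouring points in curve
    order (one-sided at sequence ends).  Surface tangents: the two leading
    principal directions of the centred k-nearest within-patch neighbourhood.
    """
    coords = config.coords
    idx = {p.label: i for i, p in enumerate(template.points)}
    frames: dict[str, np.ndarray] = {}

    curve_points = {
        p.label for p in template.points if p.role == "curve-semilandmark"
    }
    for seq in template.curves.values():
        pts = np.array([coords[idx[lab]] for lab in seq])
        for pos, lab in enumerate(seq):
            if lab not in curve_points or lab in frames:
                continue
            lo = max(pos - 1, 0)
            hi = min(pos + 1, len(seq) - 1)
            frames[lab] = _normalize(pts[hi] - pts[lo])[None, :]

    for patch, members in template.surface_patches.items():
        if len(members) < 3:
            raise ValueError(
                f"patch {patch!r} has {len(members)} points; need at least 3"
            )
        pts = np.array([coords[idx[lab]] for lab in members])
        for lab in members:
            if template.points[idx[lab]].role != "surface-semilandmark":
                continue
            x = coords[idx[lab]]
            d = np.linalg.norm(pts - x, axis=1)
            order = np.argsort(d)[: min(k_neighbors + 1, len(members))]
            nb = pts[order]
            nb = nb - nb.mean(axis=0)
            _, _, vt = np.linalg.svd(nb, full_matrices=False)
            frames[lab] = vt[:2]

    return TangentFrame(tangents=frames)


def _tangent_basis(
    template: TemplateDefinition, frames: TangentFrame
) -> tuple[np.ndarray, list[int]]:
    """(3K x q) matrix of sliding directions (x/y/z blocks) and the point
    index of each column."""
    k = template.size
    cols: list[np.ndarray] = []
    owners: list[int] = []
    for i, p in enumerate(template.points):
        dirs = frames.directions(p.label)
        if dirs is None:
            continue
        for u in dirs:
            col = np.zeros(3 * k)
            col[i] = u[0]
            col[k + i] = u[1]
            col[2 * k + i] = u[2]
            cols.append(col)
            owners.append(i)
    if not cols:
        return np.zeros((3 * k, 0)), []
    return np.column_stack(cols), owners


def relax_configuration(
    config: LandmarkConfiguration,
    reference: np.ndarray,
    frames: TangentFrame,
    template: TemplateDefinition,
    bem: BendingEnergyMatrix | None = None,
    displacement_cap: float | None = None,
) -> LandmarkConfiguration:
    """Slide semilandmarks of ``config`` along their tangents to minimize
    bending energy relative to ``reference``.

    Closed-form generalized-least-squares solve per pass: with B the
    bending-energy matrix of the reference and T the tangent basis, the
    sliding amplitudes are t = -(T' B3 T)^{-1} T' B3 y.  Fixed landmarks are
    untouched.  Displacements are capped (default: twice the median
    nearest-neighbour spacing) by uniform scaling, which preserves the
    energy decrease of the convex objective.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != config.coords.shape:
        raise ValueError("reference/configuration shape mismatch")
    if bem is None:
        bem = bending_energy_matrix(reference)
    k = template.size
    t_basis, _ = _tangent_basis(template, frames)
    if t_basis.shape[1] == 0:
        return LandmarkConfiguration(config.specimen_id, config.coords.copy(), template)

    y = config.coords.T.reshape(-1)  # [x block | y block | z block]
    b = bem.matrix
    # block-diagonal B3 products without materializing 3K x 3K
    bt = np.vstack([b @ t_basis[d * k : (d + 1) * k] for d in range(3)])
    lhs = t_basis.T @ bt
    rhs = -bt.T @ y
    try:
        t = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError:
        logger.warning(
            "singular sliding system for %s; using least-squares fallback",
            config.specimen_id,
        )
        t, *_ = np.linalg.lstsq(lhs, rhs, rcond=None)

    displacement = (t_basis @ t).reshape(3, k).T  # (K, 3)

    if displacement_cap is None:
        from scipy.spatial.distance import cdist

        d = cdist(config.coords, config.coords)
        np.fill_diagonal(d, np.inf)
        displacement_cap = 2.0 * float(np.median(d.min(axis=1)))
    max_disp = float(np.linalg.norm(displacement, axis=1).max())
    if max_disp > displacement_cap > 0:
        scale = displacement_cap / max_disp
        logger.debug(
            "capping sliding displacement for %s (%.3g -> %.3g mm)",
            config.specimen_id,
            max_disp,
            displacement_cap,
        )
        displacement = displacement * scale

    new_coords = config.coords + displacement
    if bending_energy(reference, new_coords, bem) > bending_energy(
        reference, config.coords, bem
    ) + 1e-9:
        logger.warning(
            "sliding would increase bending energy for %s; keeping original",
            config.specimen_id,
        )
        new_coords = config.coords.copy()
    return LandmarkConfiguration(config.specimen_id, new_coords, template)


def _consensus_in_config_space(
    consensus: np.ndarray, coords: np.ndarray
) -> np.ndarray:
    """Map the unit-size consensus into a configuration's own coordinate
    frame (rotate, rescale to the configuration's centroid size, translate
    to its centroid) so relaxation can run in specimen space and leave fixed
    landmarks bit-identical."""
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cs = np.sqrt(np.sum(centered**2))
    cons = consensus - consensus.mean(axis=0)
    cons = cons / np.sqrt(np.sum(cons**2))
    rot = optimal_rotation(cons, centered / cs)
    return cons @ rot * cs + centroid


def slide_sample(
    sample: Sample,
    outer_iterations: int = DEFAULT_OUTER_ITERATIONS,
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
    tolerance: float | None = None,
    displacement_cap: float | None = None,
    seed: int | None = None,
) -> tuple[Sample, SlidingReport]:
    """Relax all semilandmarks of a sample against recursive updates of the
    Procrustes consensus.

    Each outer iteration: GPA consensus of the current configurations; the
    consensus is mapped into every specimen's coordinate frame; tangent
    frames are re-estimated; each specimen relaxes toward its mapped
    consensus.  Stops after ``outer_iterations`` or when the largest
    per-pass displacement falls below ``tolerance`` (default 1e-4 of the
    mean centroid size).  If the total bending energy rises between
    iterations the best iterate is returned with a warning.

    The procedure is deterministic; ``seed`` is accepted for interface
    uniformity only.
    """
    if len(sample) < 2:
        raise ValueError("sliding needs at least 2 configurations")
    template = sample.template
    configs = [
        LandmarkConfiguration(c.specimen_id, c.coords.copy(), template)
        for c in sample.configurations
    ]
    mean_cs = float(np.mean([centroid_size(c.coords) for c in configs]))
    if tolerance is None:
        tolerance = 1e-4 * mean_cs

    energies: list[float] = []
    best_energy = np.inf
    best_configs = configs
    max_disp = 0.0
    iterations = 0
    for iterations in range(1, outer_iterations + 1):
        gpa = gpa_align([c.coords for c in configs])
        new_configs = []
        total_energy = 0.0
        max_disp = 0.0
        for c in configs:
            reference = _consensus_in_config_space(gpa.consensus, c.coords)
            bem = bending_energy_matrix(reference)
            frames = estimate_tangent_frames(c, template, k_neighbors)
            relaxed = relax_configuration(
                c, reference, frames, template, bem=bem,
                displacement_cap=displacement_cap,
            )
            disp = float(np.linalg.norm(relaxed.coords - c.coords, axis=1).max())
            max_disp = max(max_disp, disp)
            total_energy += bending_energy(reference, relaxed.coords, bem)
            new_configs.append(relaxed)
        if total_energy > best_energy * (1 + 1e-6) + 1e-12:
            # consensus update pushed energy up: converged (tiny rise) or
            # oscillating (substantive rise); either way keep the best iterate
            if total_energy > best_energy * 1.001:
                warnings.warn(
                    "sliding energy oscillates between consensus updates; "
                    "returning best iterate",
                    stacklevel=2,
                )
            break
        energies.append(total_energy)
        best_energy = total_energy
        best_configs = new_configs
        configs = new_configs
        if max_disp < tolerance:
            break

    slid = Sample(best_configs, dict(sample.metadata), template, sample.region)
    report = SlidingReport(
        iterations_run=iterations,
        energy_per_iteration=energies,
        max_displacement_mm=max_disp,
    )
    return slid, report
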