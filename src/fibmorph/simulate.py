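"""Synthetic landmark samples with known ground truth.

The generator emulates the statistical structure the analysis assumes for
fibular epiphyses: a two-region landmark template (two deformed-ellipsoid
"epiphyses" carrying fixed landmarks, ordered curves, and surface patches),
per-sex shifts in log centroid size, a common allometric slope, optional
subtle sex-specific and population-specific shape offsets — all smooth
low-frequency fields over the base geometry — plus isotropic per-landmark
Gaussian digitization noise and a random rigid nuisance motion per specimen
(rotations only; all specimens are left-side by contract).

Every specimen's generating values (true lnCS, sex, population) are
returned as ground truth for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import special_ortho_group

from .io import (
    LandmarkConfiguration,
    Sample,
    SpecimenMetadata,
    TemplateDefinition,
    TemplatePoint,
)
from .procrustes import centroid_size

# study-like cell sizes: (population, sex) -> n
STUDY_LIKE_GROUPS: dict[tuple[str, str], int] = {
    ("ER", "F"): 24,
    ("ER", "M"): 23,
    ("SAR", "F"): 29,
    ("SAR", "M"): 43,
    ("SA", "F"): 10,
    ("SA", "M"): 7,
}


@dataclass
class SimulationParams:
    n_per_group: dict[tuple[str, str], int]
    template: TemplateDefinition
    base_coords: np.ndarray  # (K, 3), mm
    lnCS_mean: float
    lnCS_sex_shift: float  # added to males
    lnCS_sd: float
    allometric_slope: np.ndarray  # (3K,), mm shape change per unit lnCS
    sex_shape_shift: np.ndarray  # (3K,), mm, added to males
    population_shape_shifts: dict[str, np.ndarray]
    landmark_noise_sd: float  # mm, isotropic per coordinate
    seed: int = 0

    def __post_init__(self) -> None:
        k3 = 3 * self.base_coords.shape[0]
        if self.allometric_slope.size != k3 or self.sex_shape_shift.size != k3:
            raise ValueError("effect vectors must have dimension 3K")
        for pop, v in self.population_shape_shifts.items():
            if v.size != k3:
                raise ValueError(f"population shift {pop!r} must have dimension 3K")
        if self.lnCS_sd < 0 or self.landmark_noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("cell sizes must be non-negative")


@dataclass
class GroundTruth:
    table: pd.DataFrame  # specimen_id, sex, population, true_lncs
    params: SimulationParams

    def lncs_of(self, specimen_id: str) -> float:
        row = self.table.loc[self.table.specimen_id == specimen_id]
        return float(row.true_lncs.iloc[0])


def _fibonacci_sphere(n: int, offset: float = 0.5) -> np.ndarray:
    """Quasi-uniform directions on the unit sphere."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + offset) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _smooth_bump(directions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Low-order radial modulation making an ellipsoid mildly asymmetric."""
    c = rng.normal(scale=0.06, size=6)
    x, y, z = directions.T
    return 1.0 + c[0] * x + c[1] * y + c[2] * z + c[3] * x * y + c[4] * y * z + c[5] * (
        x * x - z * z
    )


def _arc_on_lobe(
    start: np.ndarray, end: np.ndarray, n: int, radii: np.ndarray, center: np.ndarray
) -> np.ndarray:
    """Interior points of a surface arc between two lobe points (spherical
    interpolation in the lobe's normalized frame)."""
    a = (start - center) / radii
    b = (end - center) / radii
    a, b = a / np.linalg.norm(a), b / np.linalg.norm(b)
    omega = np.arccos(np.clip(a @ b, -1.0, 1.0))
    ts = np.linspace(0, 1, n + 2)[1:-1]
    if omega < 1e-9:
        dirs = np.outer(1 - ts, a) + np.outer(ts, b)
    else:
        dirs = (
            np.outer(np.sin((1 - ts) * omega), a) + np.outer(np.sin(ts * omega), b)
        ) / np.sin(omega)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return center + dirs * radii


def build_base_template(
    n_curve_pts: int = 25,
    n_surface_pts: int = 101,
    seed: int = 0,
) -> tuple[TemplateDefinition, np.ndarray]:
    """Procedural two-epiphysis base geometry and its template definition.

    Two deformed ellipsoid lobes stand in for the proximal and distal
    epiphyses; each carries fixed landmarks, at least one ordered curve
    along a surface arc, and a quasi-uniform surface patch.  Curve and
    surface point counts are split between the lobes in the same proportion
    as the anatomical template (6:19 and 37:64).  Deterministic given seed.
    """
    if n_curve_pts < 2 or n_surface_pts < 6:
        raise ValueError("need at least 2 curve and 6 surface points")
    rng = np.random.default_rng(seed)

    lobes = {
        "proximal": {
            "center": np.array([0.0, 0.0, 35.0]),
            "radii": np.array([12.0, 10.0, 14.0]),
            "n_fixed": 6,
            "n_curve": max(1, round(n_curve_pts * 6 / 25)),
            "n_surface": max(3, round(n_surface_pts * 37 / 101)),
        },
        "distal": {
            "center": np.array([0.0, 0.0, -35.0]),
            "radii": np.array([10.0, 8.0, 16.0]),
            "n_fixed": 10,
            "n_curve": 0,  # remainder
            "n_surface": 0,  # remainder
        },
    }
    lobes["distal"]["n_curve"] = n_curve_pts - lobes["proximal"]["n_curve"]
    lobes["distal"]["n_surface"] = n_surface_pts - lobes["proximal"]["n_surface"]
    if lobes["distal"]["n_curve"] < 1 or lobes["distal"]["n_surface"] < 3:
        raise ValueError("too few curve/surface points for two regions")

    points: list[TemplatePoint] = []
    coords: list[np.ndarray] = []
    curves: dict[str, list[str]] = {}

    for region, spec in lobes.items():
        tag = region[0].upper()
        center, radii = spec["center"], spec["radii"]

        fixed_dirs = _fibonacci_sphere(spec["n_fixed"], offset=0.31)
        fixed_dirs *= _smooth_bump(fixed_dirs, rng)[:, None]
        fixed_labels = []
        for j, d in enumerate(fixed_dirs, start=1):
            lab = f"{tag}_fix{j}"
            fixed_labels.append(lab)
            points.append(TemplatePoint(lab, "fixed", region, f"{region} fixed {j}"))
            coords.append(center + d * radii)

        # split the lobe's curve budget into arcs between fixed landmark pairs
        n_curve = spec["n_curve"]
        arc_specs = []
        if n_curve <= 3:
            arc_specs = [(fixed_labels[0], fixed_labels[1], n_curve)]
        else:
            half = n_curve // 2
            arc_specs = [
                (fixed_labels[0], fixed_labels[1], half),
                (fixed_labels[2], fixed_labels[3], n_curve - half),
            ]
        for a_lab, b_lab, n in arc_specs:
            if n == 0:
                continue
            cid = f"{tag}_curve_{a_lab}_{b_lab}"
            start = coords[[p.label for p in points].index(a_lab)]
            end = coords[[p.label for p in points].index(b_lab)]
            arc = _arc_on_lobe(start, end, n, radii, center)
            seq = [a_lab]
            for j, pt in enumerate(arc, start=1):
                lab = f"{cid}_s{j}"
                points.append(
                    TemplatePoint(lab, "curve-semilandmark", region, f"{region} arc")
                )
                coords.append(pt)
                seq.append(lab)
            seq.append(b_lab)
            curves[cid] = seq

        patch = f"{tag}_surface"
        surf_dirs = _fibonacci_sphere(spec["n_surface"], offset=0.77)
        surf_dirs *= _smooth_bump(surf_dirs, rng)[:, None]
        for j, d in enumerate(surf_dirs, start=1):
            lab = f"{patch}_s{j}"
            points.append(
                TemplatePoint(
                    lab, "surface-semilandmark", region, f"{region} surface", patch
                )
            )
            coords.append(center + d * radii)

    patches: dict[str, list[str]] = {}
    for p in points:
        if p.patch:
            patches.setdefault(p.patch, []).append(p.label)
    template = TemplateDefinition(points=points, curves=curves, surface_patches=patches)
    template.validate()
    return template, np.array(coords)


def smooth_field(
    base_coords: np.ndarray,
    rng: np.random.Generator,
    magnitude: float,
) -> np.ndarray:
    """Smooth low-frequency 3K displacement field over the base geometry.

    Linear combination of first-order harmonics (constant, linear, and
    quadratic cross terms of the normalized coordinates) per output axis,
    scaled to the requested total norm.  White-noise fields would be
    unrealistically high-frequency for anatomical shape effects.
    """
    q = base_coords - base_coords.mean(axis=0)
    q = q / np.abs(q).max()
    x, y, z = q.T
    basis = np.column_stack(
        [np.ones_like(x), x, y, z, x * y, x * z, y * z, x * x - y * y, z * z - x * x]
    )
    coef = rng.normal(size=(basis.shape[1], 3))
    f = basis @ coef
    norm = np.linalg.norm(f)
    if norm == 0:
        return np.zeros(3 * base_coords.shape[0])
    return (f / norm * magnitude).reshape(-1)


def default_params(
    seed: int = 0,
    preset: str = "study-like",
    n_curve_pts: int = 25,
    n_surface_pts: int = 101,
) -> SimulationParams:
    """Default simulation conditions.

    ``study-like``: cell sizes mirror the study design (ER 24F/23M,
    SAR 29F/43M, SA 10F/7M); males are shifted +0.08 in lnCS (about 1.6
    within-sex SD, the size-dimorphism magnitude implied by the study's
    CS statistics); shape dimorphism is subtle relative to noise; a common
    allometric slope and small population offsets are present.

    ``null``: identical design but every effect is zero — for type-I-error
    calibration.
    """
    template, base = build_base_template(n_curve_pts, n_surface_pts, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 915]))
    cs0 = centroid_size(base)
    if preset == "study-like":
        params = SimulationParams(
            n_per_group=dict(STUDY_LIKE_GROUPS),
            template=template,
            base_coords=base,
            lnCS_mean=float(np.log(cs0)),
            lnCS_sex_shift=0.08,
            lnCS_sd=0.05,
            allometric_slope=smooth_field(base, rng, 0.10 * cs0),
            sex_shape_shift=smooth_field(base, rng, 0.005 * cs0),
            population_shape_shifts={
                "ER": smooth_field(base, rng, 0.008 * cs0),
                "SAR": smooth_field(base, rng, 0.008 * cs0),
                "SA": smooth_field(base, rng, 0.008 * cs0),
            },
            landmark_noise_sd=0.5,
            seed=seed,
        )
    elif preset == "null":
        k3 = 3 * base.shape[0]
        params = SimulationParams(
            n_per_group=dict(STUDY_LIKE_GROUPS),
            template=template,
            base_coords=base,
            lnCS_mean=float(np.log(cs0)),
            lnCS_sex_shift=0.0,
            lnCS_sd=0.05,
            allometric_slope=np.zeros(k3),
            sex_shape_shift=np.zeros(k3),
            population_shape_shifts={},
            landmark_noise_sd=0.5,
            seed=seed,
        )
    else:
        raise ValueError(f"unknown preset {preset!r}")
    return params


def simulate_sample(params: SimulationParams) -> tuple[Sample, GroundTruth]:
    """Draw a landmark sample under the generating model.

    Per specimen: lnCS ~ Normal(lnCS_mean + sex shift, lnCS_sd); the shape
    is the base geometry plus allometric, sex, and population fields plus
    isotropic noise, re-standardized to unit centroid size and scaled to
    exp(lnCS); a random rotation and translation are then applied.
    """
    if not params.n_per_group or sum(params.n_per_group.values()) == 0:
        raise ValueError("empty simulation design")
    rng = np.random.default_rng(params.seed)
    k = params.base_coords.shape[0]

    configs: list[LandmarkConfiguration] = []
    metadata: dict[str, SpecimenMetadata] = {}
    truth_rows = []
    for (population, sex), n in sorted(params.n_per_group.items()):
        pop_shift = params.population_shape_shifts.get(
            population, np.zeros(3 * k)
        ).reshape(k, 3)
        for i in range(1, n + 1):
            sid = f"{population}_{sex}_{i:03d}"
            is_male = sex == "M"
            lncs = rng.normal(
                params.lnCS_mean + (params.lnCS_sex_shift if is_male else 0.0),
                params.lnCS_sd,
            )
            shape = params.base_coords + params.allometric_slope.reshape(k, 3) * (
                lncs - params.lnCS_mean
            )
            if is_male:
                shape = shape + params.sex_shape_shift.reshape(k, 3)
            shape = shape + pop_shift
            if params.landmark_noise_sd > 0:
                shape = shape + rng.normal(scale=params.landmark_noise_sd, size=(k, 3))
            centered = shape - shape.mean(axis=0)
            unit = centered / np.sqrt(np.sum(centered**2))
            coords = unit * np.exp(lncs)

            rotation = special_ortho_group.rvs(3, random_state=rng)
            translation = rng.uniform(-10, 10, size=3) * np.exp(lncs)
            coords = coords @ rotation.T + translation

            configs.append(LandmarkConfiguration(sid, coords, params.template))
            metadata[sid] = SpecimenMetadata(
                specimen_id=sid,
                sex=sex,
                population=population,
                age_years=int(rng.integers(17, 91)),
            )
            truth_rows.append(
                {
                    "specimen_id": sid,
                    "sex": sex,
                    "population": population,
                    "true_lncs": float(lncs),
                }
            )

    sample = Sample(configs, metadata, params.template, region="both")
    truth = GroundTruth(table=pd.DataFrame(truth_rows), params=params)
    return sample, truth
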