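import numpy as np
import pytest

from fibmorph.io import (
    LandmarkConfiguration,
    Sample,
    SpecimenMetadata,
    TemplateDefinition,
    TemplatePoint,
)


def make_toy_template(
    n_fixed: int = 4, n_curve: int = 3, n_surface: int = 6, region: str = "proximal"
) -> TemplateDefinition:
    """Small single-region template: a curve between two fixed points and one
    surface patch."""
    points = [
        TemplatePoint(f"F{i}", "fixed", region, f"fixed {i}") for i in range(1, n_fixed + 1)
    ]
    seq = ["F1"]
    for i in range(1, n_curve + 1):
        lab = f"c{i}"
        points.append(TemplatePoint(lab, "curve-semilandmark", region, "arc"))
        seq.append(lab)
    seq.append("F2")
    patch = {}
    for i in range(1, n_surface + 1):
        lab = f"s{i}"
        points.append(
            TemplatePoint(lab, "surface-semilandmark", region, "patch", "patchA")
        )
    patch["patchA"] = [f"s{i}" for i in range(1, n_surface + 1)]
    t = TemplateDefinition(points=points, curves={"arc": seq}, surface_patches=patch)
    t.validate()
    return t


def make_toy_coords(template: TemplateDefinition, rng: np.random.Generator) -> np.ndarray:
    """Random non-degenerate geometry for a toy template: fixed points well
    spread, curve points on a line between F1 and F2, surface points on a
    sphere cap."""
    k = template.size
    coords = np.zeros((k, 3))
    idx = {p.label: i for i, p in enumerate(template.points)}
    fixed = [p for p in template.points if p.role == "fixed"]
    base = np.array(
        [[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10], [10, 10, 0], [10, 0, 10]]
    )
    for j, p in enumerate(fixed):
        coords[idx[p.label]] = base[j % len(base)] + rng.normal(scale=0.3, size=3)
    for cid, seq in template.curves.items():
        start, end = coords[idx[seq[0]]], coords[idx[seq[-1]]]
        interior = [lab for lab in seq[1:-1]]
        for m, lab in enumerate(interior, start=1):
            t = m / (len(interior) + 1)
            bow = np.array([0.0, 2.0 * np.sin(np.pi * t), 0.0])
            coords[idx[lab]] = (1 - t) * start + t * end + bow
    for patch, members in template.surface_patches.items():
        n = len(members)
        for m, lab in enumerate(members):
            theta = 2 * np.pi * m / n
            r = 4.0 + 0.5 * np.cos(3 * theta)
            coords[idx[lab]] = np.array(
                [5 + r * np.cos(theta), 5 + r * np.sin(theta), 6 + 0.3 * np.sin(2 * theta)]
            )
    return coords


def make_sample(
    template: TemplateDefinition,
    coord_list: list[np.ndarray],
    sexes: list[str] | None = None,
) -> Sample:
    configs, metadata = [], {}
    for i, coords in enumerate(coord_list):
        sid = f"spec{i:03d}"
        configs.append(LandmarkConfiguration(sid, coords, template))
        metadata[sid] = SpecimenMetadata(
            sid, (sexes[i] if sexes else ("M" if i % 2 else "F")), "POP", 30
        )
    return Sample(configs, metadata, template, template.points[0].region)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


@pytest.fixture
def toy_template() -> TemplateDefinition:
    return make_toy_template()


@pytest.fixture
def toy_coords(toy_template, rng) -> np.ndarray:
    return make_toy_coords(toy_template, rng)
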