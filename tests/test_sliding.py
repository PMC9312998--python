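"""Tangent-frame estimation and sliding-semilandmark relaxation."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import fibmorph as fm
from fibmorph.io import LandmarkConfiguration, TemplateDefinition, TemplatePoint
from tests.conftest import make_sample, make_toy_coords, make_toy_template


def curve_only_template(n_interior):
    points = [
        TemplatePoint("A", "fixed", "proximal", "start"),
        TemplatePoint("B", "fixed", "proximal", "end"),
        TemplatePoint("C", "fixed", "proximal", "anchor1"),
        TemplatePoint("D", "fixed", "proximal", "anchor2"),
    ]
    seq = ["A"]
    for i in range(1, n_interior + 1):
        points.append(TemplatePoint(f"c{i}", "curve-semilandmark", "proximal", "arc"))
        seq.append(f"c{i}")
    seq.append("B")
    t = TemplateDefinition(points=points, curves={"arc": seq}, surface_patches={})
    t.validate()
    return t


class TestTangentFrames:
    def test_collinear_curve_tangents(self):
        t = curve_only_template(5)
        coords = np.zeros((t.size, 3))
        coords[0] = [0, 0, 0]  # A
        coords[1] = [6, 0, 0]  # B
        coords[2] = [0, 10, 0]  # C (off-line anchors for non-degeneracy)
        coords[3] = [0, 0, 10]  # D
        for i in range(5):
            coords[4 + i] = [i + 1.0, 0, 0]
        frames = fm.estimate_tangent_frames(
            LandmarkConfiguration("s", coords, t), t
        )
        for i in range(1, 6):
            tangent = frames.directions(f"c{i}")[0]
            np.testing.assert_allclose(np.abs(tangent), [1, 0, 0], atol=1e-8)

    def test_planar_patch_tangents_span_plane(self, rng):
        t = make_toy_template(n_surface=10)
        coords = make_toy_coords(t, rng)
        idx = {p.label: i for i, p in enumerate(t.points)}
        for lab in t.surface_patches["patchA"]:
            coords[idx[lab], 2] = 0.0  # flatten patch into z=0
        frames = fm.estimate_tangent_frames(LandmarkConfiguration("s", coords, t), t)
        for lab in t.surface_patches["patchA"]:
            pair = frames.directions(lab)
            assert pair.shape == (2, 3)
            np.testing.assert_allclose(pair[:, 2], 0, atol=1e-8)
            assert abs(pair[0] @ pair[1]) <= 1e-8
            np.testing.assert_allclose(np.linalg.norm(pair, axis=1), 1, atol=1e-8)

    def test_helix_tangents_match_analytic(self):
        """Interior tangents of a helix-sampled curve are within 5 degrees of
        the analytic derivative at 20 samples per turn."""
        n = 20
        t = curve_only_template(n)
        s = np.linspace(0, 2 * np.pi, n + 2)
        helix = np.column_stack([np.cos(s), np.sin(s), 0.3 * s])
        coords = np.zeros((t.size, 3))
        coords[0], coords[1] = helix[0], helix[-1]
        coords[2], coords[3] = [5, 0, 0], [0, 5, 0]
        coords[4:] = helix[1:-1]
        frames = fm.estimate_tangent_frames(LandmarkConfiguration("s", coords, t), t)
        for i in range(2, n):  # interior points with two curve neighbours
            analytic = np.array([-np.sin(s[i]), np.cos(s[i]), 0.3])
            analytic /= np.linalg.norm(analytic)
            estimated = frames.directions(f"c{i}")[0]
            angle = np.degrees(
                np.arccos(np.clip(abs(estimated @ analytic), -1, 1))
            )
            assert angle < 5.0

    def test_small_patch_rejected(self, rng):
        t = make_toy_template(n_surface=2)
        coords = make_toy_coords(t, rng)
        with pytest.raises(ValueError, match="at least 3"):
            fm.estimate_tangent_frames(LandmarkConfiguration("s", coords, t), t)


class TestRelaxConfiguration:
    def test_identical_to_reference_no_displacement(self, toy_template, toy_coords):
        config = LandmarkConfiguration("s", toy_coords, toy_template)
        frames = fm.estimate_tangent_frames(config, toy_template)
        relaxed = fm.relax_configuration(config, toy_coords, frames, toy_template)
        np.testing.assert_allclose(relaxed.coords, toy_coords, atol=1e-6)

    def test_tangentially_perturbed_point_returns(self, toy_template, toy_coords):
        """A single curve semilandmark nudged along its own tangent slides
        back to within 1% of its unperturbed position."""
        t = toy_template
        idx = {p.label: i for i, p in enumerate(t.points)}
        ref_config = LandmarkConfiguration("ref", toy_coords, t)
        frames = fm.estimate_tangent_frames(ref_config, t)
        tangent = frames.directions("c2")[0]
        delta = 0.4
        perturbed = toy_coords.copy()
        perturbed[idx["c2"]] += delta * tangent
        config = LandmarkConfiguration("s", perturbed, t)
        relaxed = fm.relax_configuration(
            config, toy_coords, fm.estimate_tangent_frames(config, t), t
        )
        residual = np.linalg.norm(relaxed.coords[idx["c2"]] - toy_coords[idx["c2"]])
        assert residual <= 0.01 * delta + 1e-3

    def test_matches_line_search_oracle_single_slider(self, toy_template, toy_coords):
        """With one sliding scalar free, relaxation lands where a 1-D numeric
        minimization of the bending energy lands."""
        t = toy_template
        idx = {p.label: i for i, p in enumerate(t.points)}
        config0 = LandmarkConfiguration("s", toy_coords, t)
        frames_all = fm.estimate_tangent_frames(config0, t)
        # free only c2: strip other semilandmarks' tangents
        frames = fm.TangentFrame({"c2": frames_all.directions("c2")})
        tangent = frames.directions("c2")[0]
        perturbed = toy_coords.copy()
        perturbed[idx["c2"]] += 0.5 * tangent
        bem = fm.bending_energy_matrix(toy_coords)

        def energy_at(alpha):
            trial = perturbed.copy()
            trial[idx["c2"]] = perturbed[idx["c2"]] + alpha * tangent
            return fm.bending_energy(toy_coords, trial, bem)

        oracle = minimize_scalar(energy_at, bounds=(-2, 2), method="bounded",
                                 options={"xatol": 1e-10})
        relaxed = fm.relax_configuration(
            LandmarkConfiguration("s", perturbed, t), toy_coords, frames, t, bem=bem
        )
        expected = perturbed[idx["c2"]] + oracle.x * tangent
        np.testing.assert_allclose(relaxed.coords[idx["c2"]], expected, atol=1e-5)

    def test_energy_never_increases(self, toy_template, toy_coords, rng):
        t = toy_template
        semis = [p.label for p in t.points if p.role != "fixed"]
        idx = {p.label: i for i, p in enumerate(t.points)}
        bem = fm.bending_energy_matrix(toy_coords)
        for _ in range(50):
            perturbed = toy_coords.copy()
            for lab in semis:
                perturbed[idx[lab]] += rng.normal(scale=0.3, size=3)
            config = LandmarkConfiguration("s", perturbed, t)
            frames = fm.estimate_tangent_frames(config, t)
            relaxed = fm.relax_configuration(config, toy_coords, frames, t, bem=bem)
            before = fm.bending_energy(toy_coords, perturbed, bem)
            after = fm.bending_energy(toy_coords, relaxed.coords, bem)
            assert after <= before + 1e-9

    def test_fixed_landmarks_bit_identical(self, toy_template, toy_coords, rng):
        t = toy_template
        idx = {p.label: i for i, p in enumerate(t.points)}
        perturbed = toy_coords + rng.normal(scale=0.1, size=toy_coords.shape)
        config = LandmarkConfiguration("s", perturbed, t)
        frames = fm.estimate_tangent_frames(config, t)
        relaxed = fm.relax_configuration(config, toy_coords, frames, t)
        for p in t.points:
            if p.role == "fixed":
                assert np.array_equal(relaxed.coords[idx[p.label]],
                                      perturbed[idx[p.label]])

    def test_curve_displacement_parallel_to_tangent(self, toy_template, toy_coords, rng):
        t = toy_template
        idx = {p.label: i for i, p in enumerate(t.points)}
        perturbed = toy_coords.copy()
        for p in t.points:
            if p.role != "fixed":
                perturbed[idx[p.label]] += rng.normal(scale=0.2, size=3)
        config = LandmarkConfiguration("s", perturbed, t)
        frames = fm.estimate_tangent_frames(config, t)
        relaxed = fm.relax_configuration(config, toy_coords, frames, t)
        for p in t.points:
            if p.role != "curve-semilandmark":
                continue
            d = relaxed.coords[idx[p.label]] - perturbed[idx[p.label]]
            norm = np.linalg.norm(d)
            if norm < 1e-12:
                continue
            cross = np.linalg.norm(np.cross(d, frames.directions(p.label)[0]))
            assert cross <= 1e-6 * norm


class TestSlideSample:
    def test_identical_configurations_converge_immediately(self, toy_template, toy_coords):
        sample = make_sample(toy_template, [toy_coords.copy() for _ in range(3)])
        slid, report = fm.slide_sample(sample)
        assert report.iterations_run == 1
        assert report.max_displacement_mm <= 1e-6
        for c, orig in zip(slid.configurations, sample.configurations):
            np.testing.assert_allclose(c.coords, orig.coords, atol=1e-6)

    def test_energy_non_increasing_and_deterministic(self, toy_template, toy_coords, rng):
        coords = [
            toy_coords + rng.normal(scale=0.15, size=toy_coords.shape)
            for _ in range(6)
        ]
        sample = make_sample(toy_template, coords)
        slid1, report1 = fm.slide_sample(sample, outer_iterations=3)
        energies = report1.energy_per_iteration
        assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))
        slid2, report2 = fm.slide_sample(sample, outer_iterations=3)
        for c1, c2 in zip(slid1.configurations, slid2.configurations):
            assert np.array_equal(c1.coords, c2.coords)

    def test_fixed_landmarks_unchanged_through_sliding(self, toy_template, toy_coords, rng):
        coords = [
            toy_coords + rng.normal(scale=0.1, size=toy_coords.shape)
            for _ in range(4)
        ]
        sample = make_sample(toy_template, coords)
        slid, _ = fm.slide_sample(sample)
        idx = {p.label: i for i, p in enumerate(toy_template.points)}
        for orig, new in zip(sample.configurations, slid.configurations):
            for p in toy_template.points:
                if p.role == "fixed":
                    assert np.array_equal(
                        new.coords[idx[p.label]], orig.coords[idx[p.label]]
                    )

    def test_sliding_reduces_tangential_jitter_variance(self, rng):
        """On a sample whose semilandmarks are jittered along their tangent
        directions, sliding reduces the Procrustes variance."""
        t = make_toy_template(n_fixed=5, n_curve=6, n_surface=12)
        base = make_toy_coords(t, rng)
        base_config = LandmarkConfiguration("base", base, t)
        frames = fm.estimate_tangent_frames(base_config, t)
        idx = {p.label: i for i, p in enumerate(t.points)}
        coords = []
        for _ in range(10):
            c = base.copy()
            for p in t.points:
                dirs = frames.directions(p.label)
                if dirs is None:
                    continue
                for u in dirs:
                    c[idx[p.label]] += rng.normal(scale=0.5) * u
            coords.append(c)
        sample = make_sample(t, coords)

        def procrustes_variance(s):
            res = fm.gpa_align([c.coords for c in s.configurations])
            return float(np.sum((res.aligned - res.consensus) ** 2))

        before = procrustes_variance(sample)
        slid, _ = fm.slide_sample(sample, outer_iterations=3)
        after = procrustes_variance(slid)
        assert after < before
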