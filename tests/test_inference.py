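"""Procrustes ANOVA (RRPP), centroid-size ANOVA, PC-CS correlation, and
allometric trajectory comparison."""

import numpy as np
import pytest
from scipy import stats

import fibmorph as fm
from fibmorph.ordination import PCAModel


def binomial_ci(n, p=0.05, conf=0.95):
    lo = int(stats.binom.ppf((1 - conf) / 2, n, p))
    hi = int(stats.binom.ppf(1 - (1 - conf) / 2, n, p))
    return lo, hi


def make_score_model(scores, space="shape"):
    scores = np.asarray(scores, float)
    m = scores.shape[1]
    return PCAModel(
        space=space,
        mean_vector=np.zeros(m),
        axes=np.eye(m),
        eigenvalues=scores.var(axis=0, ddof=1),
        scores=scores - scores.mean(axis=0),
        variance_fraction=np.full(m, 1.0 / m),
    )


class TestProcrustesAnovaRRPP:
    def test_univariate_degenerate_equals_classical_anova(self, rng):
        """With one varying coordinate the RRPP F equals the classical
        one-way ANOVA F."""
        y = np.zeros((12, 5))
        y[:, 2] = rng.normal(size=12) + np.repeat([0, 1.2], 6)
        labels = np.repeat(["a", "b"], 6)
        res = fm.procrustes_anova_rrpp(y, labels, n_perm=99, seed=0)
        f_classic, _ = stats.f_oneway(y[:6, 2], y[6:, 2])
        assert res.F == pytest.approx(f_classic, abs=1e-10)

    def test_ss_decomposition_conserves(self, rng):
        y = rng.normal(size=(20, 6))
        labels = np.repeat(["a", "b", "c", "d"], 5)
        res = fm.procrustes_anova_rrpp(y, labels, n_perm=99, seed=0)
        ss_total = np.sum((y - y.mean(axis=0)) ** 2)
        assert res.SS_effect + res.SS_residual == pytest.approx(
            ss_total, rel=1e-8
        )
        ratio = (res.SS_effect / res.df_effect) / (res.SS_residual / res.df_residual)
        assert res.F == pytest.approx(ratio, abs=1e-10)

    def test_pure_offset_groups_minimum_p(self, rng):
        base = rng.normal(size=(1, 4))
        y = np.vstack([np.repeat(base, 5, 0), np.repeat(base + 5.0, 5, 0)])
        y += rng.normal(scale=1e-6, size=y.shape)  # avoid 0/0 residual SS
        labels = np.repeat(["a", "b"], 5)
        n_perm = 199
        res = fm.procrustes_anova_rrpp(y, labels, n_perm=n_perm, seed=1)
        assert res.p == pytest.approx(1 / (n_perm + 1))

    def test_null_calibration(self):
        """Type-I error at alpha = 0.05 stays inside the exact binomial 95%
        interval over 200 exchangeable-null replicates."""
        n_rep = 200
        rejections = 0
        rng = np.random.default_rng(42)
        labels = np.repeat(["a", "b"], 10)
        for i in range(n_rep):
            y = rng.normal(size=(20, 4))
            res = fm.procrustes_anova_rrpp(y, labels, n_perm=199, seed=1000 + i)
            rejections += res.p <= 0.05
        lo, hi = binomial_ci(n_rep)
        assert lo <= rejections <= hi

    def test_seed_reproducibility_and_p_floor(self, rng):
        y = rng.normal(size=(14, 3))
        labels = np.repeat(["a", "b"], 7)
        r1 = fm.procrustes_anova_rrpp(y, labels, n_perm=199, seed=7)
        r2 = fm.procrustes_anova_rrpp(y, labels, n_perm=199, seed=7)
        assert r1.p == r2.p
        assert r1.p >= 1 / 200

    def test_single_level_rejected(self, rng):
        with pytest.raises(ValueError):
            fm.procrustes_anova_rrpp(rng.normal(size=(6, 3)), ["a"] * 6, n_perm=9)


class TestCsAnova:
    def test_closed_form_arithmetic(self):
        """Groups {1,2,3} and {4,5,6}: F = 13.5 with df (1, 4)."""
        res, posthoc, box = fm.anova_cs(
            np.array([1.0, 2, 3, 4, 5, 6]), np.repeat(["a", "b"], 3)
        )
        assert res.F == pytest.approx(13.5)
        assert (res.df_effect, res.df_residual) == (1, 4)
        assert res.p == pytest.approx(stats.f.sf(13.5, 1, 4))
        assert len(posthoc) == 1
        assert set(box) == {"a", "b"}
        assert box["a"]["median"] == 2.0

    def test_identical_groups_f_zero(self):
        res, _, _ = fm.anova_cs(
            np.array([5.0, 6, 7, 5, 6, 7]), np.repeat(["a", "b"], 3)
        )
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_small_level_excluded_with_warning(self):
        cs = np.array([1.0, 2, 3, 4, 5, 99])
        labels = np.array(["a", "a", "a", "b", "b", "c"])
        with pytest.warns(UserWarning, match="c"):
            res, _, _ = fm.anova_cs(cs, labels)
        assert res.df_residual == 3  # 5 obs, 2 levels

    def test_tukey_flags_separated_pair(self, rng):
        cs = np.concatenate([rng.normal(100, 1, 20), rng.normal(110, 1, 20),
                             rng.normal(100.2, 1, 20)])
        labels = np.repeat(["a", "b", "c"], 20)
        _, posthoc, _ = fm.anova_cs(cs, labels)
        rej = {tuple(sorted((r["group1"], r["group2"]))): r["reject"]
               for _, r in posthoc.iterrows()}
        assert rej[("a", "b")] and rej[("b", "c")]
        assert not rej[("a", "c")]


class TestCorrelation:
    def test_proportional_scores_r_one(self):
        cs = np.linspace(90, 110, 10)
        model = make_score_model(np.column_stack([2.5 * cs, cs[::-1]]))
        res = fm.correlate_pc_cs(model, cs, [0])[0]
        assert res.r == pytest.approx(1.0)

    def test_orthogonal_scores_r_zero(self):
        cs = np.array([1.0, -1, 1, -1, 1, -1])
        scores = np.column_stack([np.array([1.0, 1, -1, -1, 1, -1]) * 0 +
                                  np.array([1.0, -1, -1, 1, 1, -1]) * 0 +
                                  np.array([2.0, 2, -1, -1, -2, 0])])
        # construct exactly orthogonal scores to cs
        scores[:, 0] -= (scores[:, 0] @ cs) / (cs @ cs) * cs
        scores[:, 0] -= scores[:, 0].mean() - 0  # keep centered against constant
        # re-orthogonalize after centering
        scores[:, 0] -= (scores[:, 0] @ (cs - cs.mean())) / np.sum(
            (cs - cs.mean()) ** 2
        ) * (cs - cs.mean())
        model = make_score_model(scores)
        res = fm.correlate_pc_cs(model, cs, [0])[0]
        assert abs(res.r) <= 1e-10

    def test_direct_covariance_oracle(self, rng):
        cs = rng.uniform(80, 120, 10)
        scores = rng.normal(size=(10, 2))
        model = make_score_model(scores)
        res = fm.correlate_pc_cs(model, cs, [0, 1])
        for j, r in enumerate(res):
            s = model.scores[:, j]
            num = np.sum((s - s.mean()) * (cs - cs.mean()))
            den = np.sqrt(np.sum((s - s.mean()) ** 2) * np.sum((cs - cs.mean()) ** 2))
            assert r.r == pytest.approx(num / den, abs=1e-12)


class TestTrajectories:
    def test_exact_linear_scores_recover_slopes(self, rng):
        cs = np.concatenate([rng.uniform(90, 110, 10), rng.uniform(95, 115, 10)])
        labels = np.repeat(["F", "M"], 10)
        slopes = {"F": np.array([0.5, -0.2, 0.0]), "M": np.array([0.5, -0.2, 0.0])}
        intercepts = {"F": np.array([1.0, 2.0, 3.0]), "M": np.array([0.0, 1.0, -1.0])}
        scores = np.vstack(
            [intercepts[g] + c * slopes[g] for g, c in zip(labels, cs)]
        )
        model = make_score_model(scores)
        trajectories = {
            t.group: t
            for t in fm.fit_allometric_trajectories(model, cs, labels)
        }
        for g in ("F", "M"):
            np.testing.assert_allclose(trajectories[g].slope_vector, slopes[g], atol=1e-9)
            expected_len = np.linalg.norm(slopes[g]) * np.ptp(cs[labels == g])
            assert trajectories[g].length == pytest.approx(expected_len, abs=1e-9)

    def test_univariate_ols_oracle_per_column(self, rng):
        cs = rng.uniform(80, 120, 12)
        scores = rng.normal(size=(12, 4))
        model = make_score_model(scores)
        traj = fm.fit_allometric_trajectories(model, cs, ["g"] * 12)[0]
        for j in range(4):
            slope_oracle = stats.linregress(cs, model.scores[:, j]).slope
            assert traj.slope_vector[j] == pytest.approx(slope_oracle, abs=1e-10)

    def test_duplicated_group_identical_trajectories(self, rng):
        cs = rng.uniform(90, 110, 8)
        scores = rng.normal(size=(8, 3))
        model = make_score_model(np.vstack([scores, scores]))
        both = fm.fit_allometric_trajectories(
            model, np.concatenate([cs, cs]), np.repeat(["a", "b"], 8)
        )
        np.testing.assert_allclose(both[0].slope_vector, both[1].slope_vector, atol=1e-12)
        assert both[0].length == pytest.approx(both[1].length)

    def test_identical_groups_angle_zero_p_high(self, rng):
        cs = rng.uniform(90, 110, 10)
        scores = np.column_stack([0.3 * cs, -0.1 * cs]) + rng.normal(
            scale=1e-9, size=(10, 2)
        )
        cs2, scores2 = np.concatenate([cs, cs]), np.vstack([scores, scores])
        labels = np.repeat(["a", "b"], 10)
        comp = fm.compare_trajectories(scores2, cs2, labels, "a", "b",
                                       n_perm=199, seed=3)
        assert comp.angle_deg <= 1e-6
        assert comp.p_angle > 0.5

    def test_orthogonal_slopes_angle_90(self):
        a = fm.AllometricTrajectory("a", np.array([1.0, 0, 0]), np.zeros(3), 1.0)
        b = fm.AllometricTrajectory("b", np.array([0.0, 1.0, 0]), np.zeros(3), 1.0)
        from fibmorph.inference import _angle_deg

        assert _angle_deg(a.slope_vector, b.slope_vector) == pytest.approx(90.0)

    def test_angle_symmetric_and_scale_invariant(self, rng):
        from fibmorph.inference import _angle_deg

        u, v = rng.normal(size=3), rng.normal(size=3)
        assert _angle_deg(u, v) == pytest.approx(_angle_deg(v, u))
        assert _angle_deg(3.7 * u, 3.7 * v) == pytest.approx(_angle_deg(u, v))

    def test_null_calibration_angle_test(self):
        """Angle-permutation rejection rate at alpha = 0.05 within the exact
        binomial 95% interval over 200 exchangeable two-group replicates."""
        n_rep = 200
        rng = np.random.default_rng(99)
        labels = np.repeat(["a", "b"], 10)
        rejections = 0
        for i in range(n_rep):
            cs = rng.uniform(90, 110, 20)
            scores = np.column_stack([0.2 * cs, -0.1 * cs]) + rng.normal(
                scale=1.0, size=(20, 2)
            )
            comp = fm.compare_trajectories(
                scores, cs, labels, "a", "b", n_perm=99, seed=5000 + i
            )
            rejections += comp.p_angle <= 0.05
        lo, hi = binomial_ci(n_rep)
        assert lo <= rejections <= hi
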