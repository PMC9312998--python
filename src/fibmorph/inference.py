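"""Permutation-based and classical inference on shape, form, and size.

* Procrustes ANOVA with residual randomization (RRPP): sums of squares in
  the flattened coordinate space, null distribution from permuting
  reduced-model (grand-mean) residuals.
* Classical one-way ANOVA on centroid size with Tukey HSD post hoc
  comparisons and box-plot summaries.
* Pearson correlation of PC scores with centroid size.
* Allometric trajectories: per-group multivariate regression of all PC
  scores on centroid size, compared between groups by the angle between
  slope vectors and by trajectory length, with label-permutation p-values.

All permutation p-values use the add-one convention
p = (1 + #{stat* >= stat}) / (n_perm + 1), so p >= 1/(n_perm+1) > 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ordination import PCAModel

DEFAULT_PERMUTATIONS = 1000


@dataclass
class AnovaResult:
    factor: str
    SS_effect: float
    SS_residual: float
    df_effect: int
    df_residual: int
    F: float
    p: float
    n_permutations: int = 0
    seed: int | None = None


@dataclass
class CorrelationResult:
    pc_index: int
    r: float
    p: float


@dataclass
class AllometricTrajectory:
    group: str
    slope_vector: np.ndarray  # (m,)
    intercept_vector: np.ndarray  # (m,)
    length: float  # ||slope|| * CS range of the group


@dataclass
class TrajectoryComparison:
    pair: tuple[str, str]
    angle_deg: float
    p_angle: float
    length_difference: float
    p_length: float
    n_permutations: int
    seed: int | None = None


def _group_sums_of_squares(y: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(SS_effect, SS_residual) of the one-way group-mean model on rows of y."""
    grand = y.mean(axis=0)
    ss_total = float(np.sum((y - grand) ** 2))
    ss_residual = 0.0
    for level in np.unique(labels):
        sub = y[labels == level]
        ss_residual += float(np.sum((sub - sub.mean(axis=0)) ** 2))
    return ss_total - ss_residual, ss_residual


def procrustes_anova_rrpp(
    data: np.ndarray,
    labels: np.ndarray,
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    factor: str = "group",
) -> AnovaResult:
    """One-way Procrustes ANOVA with residual randomization.

    ``data`` is N x D flattened shape (or score) coordinates.  The observed
    F compares the group-mean model with the grand-mean model using summed
    squared distances; the null distribution permutes grand-mean residuals
    (for the one-way design this equals permuting rows) and refits.
    """
    y = np.atleast_2d(np.asarray(data, dtype=float))
    if y.shape[0] != len(labels):
        raise ValueError("data rows and labels differ in length")
    labels = np.asarray(labels)
    levels, counts = np.unique(labels, return_counts=True)
    if len(levels) < 2:
        raise ValueError("need at least 2 factor levels")
    if counts.min() < 2:
        raise ValueError("every level needs at least 2 specimens")

    n = y.shape[0]
    df_effect = len(levels) - 1
    df_residual = n - len(levels)

    ss_effect, ss_residual = _group_sums_of_squares(y, labels)
    f_obs = (ss_effect / df_effect) / (ss_residual / df_residual)

    rng = np.random.default_rng(seed)
    grand = y.mean(axis=0)
    residuals = y - grand
    exceed = 0
    for _ in range(n_perm):
        permuted = grand + residuals[rng.permutation(n)]
        sse, ssr = _group_sums_of_squares(permuted, labels)
        f_star = (sse / df_effect) / (ssr / df_residual)
        if f_star >= f_obs:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)

    return AnovaResult(
        factor=factor,
        SS_effect=ss_effect,
        SS_residual=ss_residual,
        df_effect=df_effect,
        df_residual=df_residual,
        F=f_obs,
        p=p,
        n_permutations=n_perm,
        seed=seed,
    )


def _boxplot_stats(values: np.ndarray) -> dict[str, float | list[float]]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inliers = values[(values >= lo) & (values <= hi)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inliers.min()),
        "whisker_high": float(inliers.max()),
        "outliers": [float(v) for v in values[(values < lo) | (values > hi)]],
    }


def anova_cs(
    centroid_sizes: np.ndarray,
    labels: np.ndarray,
    factor: str = "group",
    posthoc: str = "tukey",
) -> tuple[AnovaResult, pd.DataFrame, dict[str, dict]]:
    """Classical one-way ANOVA on centroid size with pairwise post hoc tests.

    Returns the ANOVA result, a post hoc table (Tukey HSD by default,
    Bonferroni-adjusted Welch t-tests as the alternative), and per-level
    box-plot summaries (median, quartiles, whiskers, outliers).  Levels with
    fewer than 2 observations are excluded with a warning.
    """
    cs = np.asarray(centroid_sizes, dtype=float)
    labels = np.asarray(labels)
    levels, counts = np.unique(labels, return_counts=True)
    small = levels[counts < 2]
    if small.size:
        warnings.warn(
            f"excluding levels with <2 observations: {list(small)}", stacklevel=2
        )
        keep = ~np.isin(labels, small)
        cs, labels = cs[keep], labels[keep]
        levels = np.unique(labels)
    if len(levels) < 2:
        raise ValueError("need at least 2 usable factor levels")

    groups = [cs[labels == level] for level in levels]
    df_effect = len(levels) - 1
    df_residual = len(cs) - len(levels)
    ss_effect, ss_residual = _group_sums_of_squares(cs[:, None], labels)
    f_obs = (ss_effect / df_effect) / (ss_residual / df_residual)
    p = float(stats.f.sf(f_obs, df_effect, df_residual))

    result = AnovaResult(
        factor=factor,
        SS_effect=ss_effect,
        SS_residual=ss_residual,
        df_effect=df_effect,
        df_residual=df_residual,
        F=f_obs,
        p=p,
    )

    if posthoc == "tukey":
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        hsd = pairwise_tukeyhsd(cs, labels, alpha=0.05)
        table = pd.DataFrame(
            hsd.summary().data[1:], columns=hsd.summary().data[0]
        )
    elif posthoc == "bonferroni":
        rows = []
        pairs = [
            (levels[i], levels[j])
            for i in range(len(levels))
            for j in range(i + 1, len(levels))
        ]
        for a, b in pairs:
            t, praw = stats.ttest_ind(
                cs[labels == a], cs[labels == b], equal_var=False
            )
            rows.append(
                {
                    "group1": a,
                    "group2": b,
                    "t": float(t),
                    "p-adj": min(1.0, float(praw) * len(pairs)),
                }
            )
        table = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown posthoc {posthoc!r}")

    box = {str(level): _boxplot_stats(g) for level, g in zip(levels, groups)}
    return result, table, box


def correlate_pc_cs(
    model: PCAModel, centroid_sizes: np.ndarray, pc_indices: list[int]
) -> list[CorrelationResult]:
    """Pearson correlation (two-sided) of selected PC scores with CS."""
    cs = np.asarray(centroid_sizes, dtype=float)
    if cs.std() == 0:
        raise ValueError("centroid size has zero variance")
    out = []
    for idx in pc_indices:
        scores = model.scores[:, idx]
        if scores.std() == 0:
            raise ValueError(f"PC{idx + 1} scores have zero variance")
        r, p = stats.pearsonr(scores, cs)
        out.append(CorrelationResult(pc_index=idx, r=float(r), p=float(p)))
    return out


def _fit_trajectory(
    scores: np.ndarray, cs: np.ndarray, group: str
) -> AllometricTrajectory:
    if scores.shape[0] < 3:
        raise ValueError(f"group {group!r} needs at least 3 specimens")
    if np.ptp(cs) == 0:
        raise ValueError(f"group {group!r} has constant centroid size")
    x = np.column_stack([np.ones_like(cs), cs])
    coef, *_ = np.linalg.lstsq(x, scores, rcond=None)
    slope = coef[1]
    return AllometricTrajectory(
        group=group,
        slope_vector=slope,
        intercept_vector=coef[0],
        length=float(np.linalg.norm(slope) * np.ptp(cs)),
    )


def fit_allometric_trajectories(
    model: PCAModel, centroid_sizes: np.ndarray, labels: np.ndarray
) -> list[AllometricTrajectory]:
    """Per-group ordinary least squares of the full PC score matrix on CS.

    Trajectory length is the slope norm scaled by the group's CS range (a
    measure of the magnitude of allometric variability spanned by the
    group).
    """
    cs = np.asarray(centroid_sizes, dtype=float)
    labels = np.asarray(labels)
    return [
        _fit_trajectory(model.scores[labels == g], cs[labels == g], str(g))
        for g in np.unique(labels)
    ]


def _angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm slope vector: angle undefined")
    cosine = np.clip(a @ b / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosine)))


def compare_trajectories(
    scores: np.ndarray,
    centroid_sizes: np.ndarray,
    labels: np.ndarray,
    group_a: str,
    group_b: str,
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
) -> TrajectoryComparison:
    """Permutation test on the angle between two groups' allometric slope
    vectors and on the difference of their trajectory lengths.

    Group labels are shuffled among the two groups' specimens (CS held
    fixed); both statistics are recomputed per permutation.
    """
    labels = np.asarray(labels)
    cs = np.asarray(centroid_sizes, dtype=float)
    mask = np.isin(labels, [group_a, group_b])
    sub_scores, sub_cs, sub_labels = scores[mask], cs[mask], labels[mask]

    def both_stats(lab: np.ndarray) -> tuple[float, float]:
        ta = _fit_trajectory(sub_scores[lab == group_a], sub_cs[lab == group_a], group_a)
        tb = _fit_trajectory(sub_scores[lab == group_b], sub_cs[lab == group_b], group_b)
        return (
            _angle_deg(ta.slope_vector, tb.slope_vector),
            abs(ta.length - tb.length),
        )

    angle_obs, length_obs = both_stats(sub_labels)

    rng = np.random.default_rng(seed)
    exceed_angle = exceed_length = 0
    for _ in range(n_perm):
        perm = sub_labels[rng.permutation(len(sub_labels))]
        try:
            angle_star, length_star = both_stats(perm)
        except ValueError:
            # degenerate permutation (constant CS in a group); count as extreme
            exceed_angle += 1
            exceed_length += 1
            continue
        if angle_star >= angle_obs:
            exceed_angle += 1
        if length_star >= length_obs:
            exceed_length += 1

    return TrajectoryComparison(
        pair=(group_a, group_b),
        angle_deg=angle_obs,
        p_angle=(1 + exceed_angle) / (n_perm + 1),
        length_difference=length_obs,
        p_length=(1 + exceed_length) / (n_perm + 1),
        n_permutations=n_perm,
        seed=seed,
    )
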