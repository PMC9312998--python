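"""Leave-one-out cross-validated linear discriminant sex classification.

Features are shape-space PC scores, form-space PC scores, or centroid size
alone.  The number of PCs entering the LDA is chosen within the first 10 by
balancing explained variance (70% threshold) against LOOCV accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .ordination import PCAModel

logger = logging.getLogger(__name__)

MAX_PCS = 10
VARIANCE_THRESHOLD = 0.70


@dataclass
class LdaReport:
    feature_set: str  # "shape-PCs" | "form-PCs" | "CS" | free text
    n_pcs_used: int
    cumulative_variance: float | None
    n_correct: int
    n_total: int
    accuracy_pct: float
    confusion: dict[str, dict[str, int]]  # true class -> predicted class -> count
    selection_trace: list[dict] = field(default_factory=list)
    below_variance_threshold: bool = False

    @property
    def summary(self) -> str:
        return (
            f"{self.feature_set}: {self.n_correct}/{self.n_total} "
            f"({self.accuracy_pct:.0f}%)"
        )


def _lda(priors_policy: str, classes: np.ndarray) -> LinearDiscriminantAnalysis:
    if priors_policy == "proportional":
        return LinearDiscriminantAnalysis()
    if priors_policy == "equal":
        return LinearDiscriminantAnalysis(
            priors=np.full(len(classes), 1.0 / len(classes))
        )
    raise ValueError(f"unknown priors policy {priors_policy!r}")


def loocv_lda(
    features: np.ndarray,
    labels: np.ndarray,
    priors_policy: str = "proportional",
    feature_set: str = "features",
) -> LdaReport:
    """Two-class LDA accuracy by leave-one-out cross-validation.

    For each specimen the classifier is refit on the remaining N-1 (pooled
    within-class covariance; priors proportional to training-fold class
    frequencies by default) and the held-out specimen is classified.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[0] == 1 and len(labels) > 1:
        x = x.T
    labels = np.asarray(labels)
    n = x.shape[0]
    if n != len(labels):
        raise ValueError("features and labels differ in length")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("LDA here is two-class (e.g., sex M/F)")
    if counts.min() < 2:
        raise ValueError("both classes need at least 2 members")
    if x.shape[1] >= n - 1:
        raise ValueError(
            f"{x.shape[1]} features with only {n} specimens: p must be < N-1"
        )

    predictions = np.empty(n, dtype=labels.dtype)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        clf = _lda(priors_policy, classes)
        try:
            clf.fit(x[mask], labels[mask])
        except Exception:  # singular within-class scatter: ridge-regularized refit
            logger.warning("singular pooled covariance in LOOCV fold; adding ridge")
            clf = _lda(priors_policy, classes)
            clf.set_params(solver="lsqr", shrinkage=1e-8)
            clf.fit(x[mask], labels[mask])
        predictions[i] = clf.predict(x[i : i + 1])[0]

    confusion = {
        str(t): {str(p): int(np.sum((labels == t) & (predictions == p))) for p in classes}
        for t in classes
    }
    n_correct = int(np.sum(predictions == labels))
    return LdaReport(
        feature_set=feature_set,
        n_pcs_used=x.shape[1],
        cumulative_variance=None,
        n_correct=n_correct,
        n_total=n,
        accuracy_pct=100.0 * n_correct / n,
        confusion=confusion,
    )


def select_pcs(
    model: PCAModel,
    labels: np.ndarray,
    max_pcs: int = MAX_PCS,
    variance_threshold: float = VARIANCE_THRESHOLD,
    priors_policy: str = "proportional",
) -> tuple[int, LdaReport]:
    """Choose how many leading PCs enter the LDA.

    Evaluates k = 1..min(max_pcs, available PCs, N-2) by LOOCV accuracy and
    picks the accuracy maximizer; among tied maximizers the smallest k whose
    cumulative explained variance reaches the threshold is preferred, then
    the smallest k outright.  If no candidate k reaches the variance
    threshold the report is flagged.
    """
    labels = np.asarray(labels)
    n = model.scores.shape[0]
    k_max = min(max_pcs, model.n_components, n - 2)
    if k_max < 1:
        raise ValueError("no usable principal components")

    trace: list[dict] = []
    reports: dict[int, LdaReport] = {}
    for k in range(1, k_max + 1):
        rep = loocv_lda(
            model.scores[:, :k],
            labels,
            priors_policy=priors_policy,
            feature_set=f"{model.space}-PCs",
        )
        rep.cumulative_variance = model.cumulative_variance(k)
        reports[k] = rep
        trace.append(
            {
                "k": k,
                "accuracy_pct": rep.accuracy_pct,
                "cumulative_variance": rep.cumulative_variance,
            }
        )

    best_acc = max(t["accuracy_pct"] for t in trace)
    tied = [t["k"] for t in trace if t["accuracy_pct"] == best_acc]
    reaching = [k for k in tied if reports[k].cumulative_variance >= variance_threshold]
    chosen = min(reaching) if reaching else min(tied)

    report = reports[chosen]
    report.selection_trace = trace
    if all(t["cumulative_variance"] < variance_threshold for t in trace):
        report.below_variance_threshold = True
    return chosen, report


def classify_by_cs(
    centroid_sizes: np.ndarray,
    labels: np.ndarray,
    priors_policy: str = "proportional",
) -> LdaReport:
    """LOOCV LDA on centroid size as the single feature."""
    cs = np.asarray(centroid_sizes, dtype=float).reshape(-1, 1)
    report = loocv_lda(cs, labels, priors_policy=priors_policy, feature_set="CS")
    report.n_pcs_used = 0
    return report
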