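"""Per-marker and integrative multi-marker ROC analysis.

AUC is computed by pair counting (ties count one half), which equals the
trapezoidal area under the empirical ROC. The multi-marker panel combines
z-scored markers with a ridge-stabilized logistic regression; its linear
predictor is the panel score. Confidence intervals come from a stratified
percentile bootstrap (resampling within each class); the operating point is
the Youden-optimal threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression

from .errors import ComputationError, ValidationError

N_BOOT = 2000
CI_LEVEL = 0.95
RIDGE_L2 = 1e-6


@dataclass
class RocResult:
    marker_or_panel: str
    auc: float
    ci_95: tuple[float, float]
    sensitivity: float
    specificity: float
    threshold: float
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {
            "marker_or_panel": self.marker_or_panel,
            "auc": self.auc,
            "ci_95": list(self.ci_95),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "threshold": self.threshold,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.size != labels.size:
        raise ValidationError("scores and labels differ in length")
    pos, neg = scores[labels], scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both classes must be present")
    return pos, neg


def auc_rank(scores_pos: Sequence[float],
             scores_neg: Sequence[float]) -> float:
    """AUC by pair counting: P(pos > neg) + 0.5 P(pos == neg).

    Computed via midranks of the pooled sample, O(n log n), identical to
    exhaustive pair counting including the ties-count-half convention.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float(
        (r_pos - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size)
    )


def auc_from_labels(scores, labels) -> float:
    pos, neg = _split(scores, labels)
    return auc_rank(pos, neg)


def roc_points(scores, labels) -> pd.DataFrame:
    """Empirical ROC curve: (FPR, TPR) at every distinct threshold."""
    pos, neg = _split(scores, labels)
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    rows = [(0.0, 0.0)]
    for t in thresholds:
        rows.append((float((neg >= t).mean()), float((pos >= t).mean())))
    rows.append((1.0, 1.0))
    return pd.DataFrame(rows, columns=["fpr", "tpr"]).drop_duplicates()


class MarkerPanel(BaseEstimator, ClassifierMixin):
    """Integrative multi-marker panel: z-scoring + ridge logistic score.

    scikit-learn estimator: ``fit(X, y)`` standardizes each marker (stored
    in ``center_``/``scale_``) and fits an L2-penalized logistic regression
    (penalty strength ``l2``; the tiny default only stabilizes complete
    separation). The panel score is the linear predictor
    (``decision_function``); every ROC quantity is computed from it. The
    per-marker direction is learned from data, not hard-coded.
    """

    def __init__(self, l2: float = RIDGE_L2, markers: Sequence[str] | None = None):
        self.l2 = l2
        self.markers = markers

    def fit(self, X, y) -> "MarkerPanel":
        X = self._as_matrix(X, fitting=True)
        y = np.asarray(y).astype(int)
        if X.ndim != 2:
            raise ValidationError("X must be 2-dimensional")
        if np.unique(y).size < 2:
            raise ValidationError("labels contain a single class")
        if np.isnan(X).any():
            raise ValidationError("panel markers contain missing values")
        self.center_ = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        self.scale_ = np.where(scale > 0, scale, 1.0)
        Z = (X - self.center_) / self.scale_
        # sklearn's C is the inverse L2 penalty strength (ridge by default)
        self._lr = LogisticRegression(
            C=1.0 / self.l2, solver="lbfgs", max_iter=5000
        ).fit(Z, y)
        self.weights_ = self._lr.coef_.ravel().copy()
        self.intercept_ = float(self._lr.intercept_[0])
        self.classes_ = self._lr.classes_
        return self

    def _as_matrix(self, X, fitting: bool = False) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if self.markers is not None:
                X = X[list(self.markers)]
            elif fitting:
                self.feature_names_ = list(X.columns)
            X = X.to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def decision_function(self, X) -> np.ndarray:
        self._check_fitted()
        Z = (self._as_matrix(X) - self.center_) / self.scale_
        return Z @ self.weights_ + self.intercept_

    def predict_proba(self, X) -> np.ndarray:
        score = self.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-score))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0).astype(int)

    def _check_fitted(self) -> None:
        if not hasattr(self, "weights_"):
            raise ComputationError("panel is not fitted")


def fit_panel(X, y, l2: float = RIDGE_L2,
              markers: Sequence[str] | None = None) -> MarkerPanel:
    """Thin functional wrapper over :class:`MarkerPanel`."""
    return MarkerPanel(l2=l2, markers=markers).fit(X, y)


def bootstrap_ci(
    scores,
    labels,
    n_boot: int = N_BOOT,
    level: float = CI_LEVEL,
    seed: int = 0,
) -> tuple[float, float]:
    """Stratified percentile bootstrap CI for the AUC.

    Positives and negatives are resampled within class; the interval is the
    percentile interval of the bootstrap AUC distribution. Deterministic
    under a fixed seed.
    """
    if n_boot < 200:
        raise ValidationError("n_boot must be >= 200")
    if not 0 < level < 1:
        raise ValidationError("level must be in (0, 1)")
    pos, neg = _split(scores, labels)
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        p = pos[rng.integers(0, pos.size, pos.size)]
        n = neg[rng.integers(0, neg.size, neg.size)]
        aucs[b] = auc_rank(p, n)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def youden_point(scores, labels) -> tuple[float, float, float]:
    """Operating point maximizing Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are the midpoints between consecutive distinct
    scores (plus one below the minimum and one above the maximum); a sample
    is called positive when its score >= threshold. Ties in J resolve to the
    lowest threshold. Returns (threshold, sensitivity, specificity).
    """
    pos, neg = _split(scores, labels)
    uniq = np.unique(np.concatenate([pos, neg]))
    candidates = [uniq[0] - 1.0]
    candidates.extend((uniq[:-1] + uniq[1:]) / 2.0)
    candidates.append(uniq[-1] + 1.0)
    best = (-np.inf, np.nan, np.nan, np.nan)
    for t in candidates:
        sens = float((pos >= t).mean())
        spec = float((neg < t).mean())
        j = sens + spec - 1.0
        if j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    _, t, sens, spec = best
    return float(t), sens, spec


def evaluate_scores(
    name: str,
    scores,
    labels,
    n_boot: int = N_BOOT,
    level: float = CI_LEVEL,
    seed: int = 0,
) -> RocResult:
    """AUC + bootstrap CI + Youden operating point for one score vector."""
    pos, neg = _split(scores, labels)
    auc = auc_rank(pos, neg)
    ci = bootstrap_ci(scores, labels, n_boot=n_boot, level=level, seed=seed)
    thr, sens, spec = youden_point(scores, labels)
    return RocResult(name, auc, ci, sens, spec, thr, pos.size, neg.size)


def marker_elimination(
    X: pd.DataFrame,
    y,
    l2: float = RIDGE_L2,
) -> pd.DataFrame:
    """Leave-one-marker-out panel AUCs.

    Refits the panel without each marker and reports the AUC after removal
    and its delta from the full panel (negative delta = the marker was
    contributing).
    """
    markers = list(X.columns)
    if len(markers) < 2:
        raise ValidationError("need >= 2 markers to eliminate")
    full_auc = auc_from_labels(MarkerPanel(l2=l2).fit(X, y).decision_function(X), y)
    rows = []
    for m in markers:
        rest = [c for c in markers if c != m]
        sub = X[rest]
        if len(rest) == 1:
            score = sub.iloc[:, 0].to_numpy(dtype=float)
        else:
            score = MarkerPanel(l2=l2).fit(sub, y).decision_function(sub)
        auc = auc_from_labels(score, y)
        # single-marker direction is learned: flip if below chance
        if len(rest) == 1 and auc < 0.5:
            auc = 1.0 - auc
        rows.append({"removed_marker": m, "auc_without": auc,
                     "delta_vs_full": auc - full_auc})
    out = pd.DataFrame(rows).sort_values("delta_vs_full").reset_index(drop=True)
    out.attrs["full_auc"] = full_auc
    return out


def run_panel_analysis(
    cohort_markers: pd.DataFrame,
    labels,
    n_boot: int = N_BOOT,
    level: float = CI_LEVEL,
    seed: int = 0,
    l2: float = RIDGE_L2,
) -> dict:
    """Per-marker and integrative panel ROC report.

    ``cohort_markers`` is a subjects x markers frame; ``labels`` the binary
    outcome. Single markers are oriented so AUC >= 0.5 (direction learned
    from data). Returns a dict with per-marker results, the panel result,
    the elimination table and the panel ROC curve points.
    """
    y = np.asarray(labels).astype(bool)
    per_marker = {}
    for m in cohort_markers.columns:
        vals = cohort_markers[m].to_numpy(dtype=float)
        if auc_from_labels(vals, y) < 0.5:
            vals = -vals
        per_marker[m] = evaluate_scores(m, vals, y, n_boot=n_boot,
                                        level=level, seed=seed)
    panel = MarkerPanel(l2=l2).fit(cohort_markers, y)
    score = panel.decision_function(cohort_markers)
    panel_result = evaluate_scores("panel", score, y, n_boot=n_boot,
                                   level=level, seed=seed)
    elim = marker_elimination(cohort_markers, y, l2=l2)
    return {
        "per_marker": per_marker,
        "panel": panel_result,
        "panel_model": panel,
        "elimination": elim,
        "roc_curve": roc_points(score, y),
    }
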