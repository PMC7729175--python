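"""Shrinkage-regularized LDA over stepwise-selected spatially filtered samples.

Single-epoch classification works on the flattened n_w x n_hat_t grid of
spatially filtered time samples (filter-major ordering: feature id
``f * n_hat_t + t``).  A forward-backward stepwise search picks a small
feature subset by cross-validated weighted accuracy, and a regularized linear
discriminant (covariance shrunk toward a scaled identity) with equal class
priors separates target from non-target epochs.  Equal priors keep the
decision boundary unbiased despite the 1:5 class imbalance of calibration
data; weighted accuracy scores both classes equally for the same reason.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.covariance import ledoit_wolf_shrinkage

__all__ = [
    "StepwiseConfig",
    "ClassifierModel",
    "flatten_features",
    "fit_rlda",
    "classify",
    "decision_scores",
    "stepwise_select_and_fit",
    "weighted_accuracy",
]

TARGET, NON_TARGET = "target", "non-target"


def flatten_features(projected: np.ndarray) -> np.ndarray:
    """Flatten an n_w x n_hat_t projection to a vector, filter-major order."""
    return np.asarray(projected).reshape(-1)


@dataclass(frozen=True)
class StepwiseConfig:
    """Knobs of the forward-backward stepwise search.

    ``epsilon`` is the minimum cross-validated weighted-accuracy improvement
    that justifies adding a feature (and the maximum tolerated loss for
    removing one); ``max_features`` caps the model size; ``cv_folds`` and
    ``seed`` fix the internal scoring folds for determinism.
    """

    epsilon: float = 0.001
    max_features: int = 60
    cv_folds: int = 5
    seed: int = 0
    gamma: float | None = None  # None: Ledoit-Wolf, computed once per search


@dataclass
class ClassifierModel:
    """Fitted RLDA over an ordered subset of feature ids.

    The decision rule is affine in the selected features:
    score(x) = w' x[selected] + b, label = target iff score >= 0.
    """

    selected: list[int]
    weights: np.ndarray
    bias: float
    gamma: float
    class_means: np.ndarray  # 2 x n_f: row 0 non-target, row 1 target
    pooled_covariance: np.ndarray

    def __post_init__(self) -> None:
        if len(self.selected) < 1:
            raise ValueError("model must carry at least one feature")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "selected": list(map(int, self.selected)),
            "weights": self.weights.tolist(),
            "bias": float(self.bias),
            "gamma": float(self.gamma),
            "class_means": self.class_means.tolist(),
            "pooled_covariance": self.pooled_covariance.tolist(),
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassifierModel":
        doc = json.loads(Path(path).read_text())
        return cls(selected=list(doc["selected"]),
                   weights=np.asarray(doc["weights"], dtype=float),
                   bias=float(doc["bias"]), gamma=float(doc["gamma"]),
                   class_means=np.asarray(doc["class_means"], dtype=float),
                   pooled_covariance=np.asarray(doc["pooled_covariance"],
                                                dtype=float))


def _check_two_class(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    classes = np.unique(labels)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("labels must contain both classes, coded 0/1")
    return labels


def _rlda_direction(features: np.ndarray, labels: np.ndarray,
                    gamma: float) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Core RLDA solve: returns (weights, bias, class_means, shrunk covariance)."""
    X0, X1 = features[labels == 0], features[labels == 1]
    mu = np.vstack([X0.mean(axis=0), X1.mean(axis=0)])
    n0, n1 = len(X0), len(X1)
    S = (X0 - mu[0]).T @ (X0 - mu[0]) + (X1 - mu[1]).T @ (X1 - mu[1])
    cov = S / max(n0 + n1 - 2, 1)
    p = cov.shape[0]
    target = (np.trace(cov) / p) * np.eye(p)
    shrunk = (1.0 - gamma) * cov + gamma * target
    w = np.linalg.solve(shrunk, mu[1] - mu[0])
    # Equal class priors: boundary at the midpoint between class means.
    b = -0.5 * w @ (mu[0] + mu[1])
    return w, float(b), mu, shrunk


def fit_rlda(features: np.ndarray, labels: Sequence[int],
             gamma: float | None = None,
             selected: Sequence[int] | None = None) -> ClassifierModel:
    """Fit a regularized LDA (covariance shrunk toward scaled identity).

    Parameters
    ----------
    features
        n_obs x n_f matrix (already restricted to the candidate features).
    labels
        Binary vector; 1 = target, 0 = non-target.
    gamma
        Shrinkage in [0, 1]; ``None`` uses the analytic Ledoit-Wolf estimate.
    selected
        Feature ids the columns of ``features`` refer to (bookkeeping only;
        defaults to 0..n_f-1).
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = _check_two_class(np.asarray(labels))
    if features.shape[0] < features.shape[1] + 2:
        raise ValueError("need at least n_features + 2 observations")
    if gamma is None:
        gamma = float(ledoit_wolf_shrinkage(
            features - features.mean(axis=0), assume_centered=False))
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    w, b, mu, shrunk = _rlda_direction(features, labels, gamma)
    sel = list(range(features.shape[1])) if selected is None else list(selected)
    return ClassifierModel(selected=sel, weights=w, bias=b, gamma=gamma,
                           class_means=mu, pooled_covariance=shrunk)


def decision_scores(features: np.ndarray, model: ClassifierModel,
                    full_grid: bool = False) -> np.ndarray:
    """Affine decision scores; positive means target."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    cols = model.selected if full_grid else range(len(model.selected))
    sub = features[:, list(cols)]
    if sub.shape[1] != len(model.selected):
        raise ValueError("feature vector does not cover the selected ids")
    return sub @ model.weights + model.bias


def classify(epoch_features: np.ndarray, model: ClassifierModel) -> str:
    """Label one epoch's flattened feature grid as target or non-target."""
    grid = flatten_features(epoch_features)
    if grid.size <= max(model.selected):
        raise ValueError(
            f"feature grid of size {grid.size} lacks id {max(model.selected)}")
    score = float(grid[model.selected] @ model.weights + model.bias)
    return TARGET if score >= 0 else NON_TARGET


def weighted_accuracy(labels: np.ndarray, predicted: np.ndarray) -> float:
    """0.5 * (target accuracy + non-target accuracy), as a fraction."""
    labels = np.asarray(labels).astype(int)
    predicted = np.asarray(predicted).astype(int)
    accs = [np.mean(predicted[labels == c] == c) for c in (0, 1)]
    return 0.5 * float(sum(accs))


class _FoldScorer:
    """Cross-validated weighted accuracy for feature subsets, with per-fold
    class scatter matrices precomputed once so each candidate evaluation is a
    small dense solve instead of a pass over the data."""

    def __init__(self, features: np.ndarray, labels: np.ndarray,
                 n_folds: int, seed: int, gamma: float):
        self.X = features
        self.y = labels
        self.gamma = gamma
        rng = np.random.default_rng(seed)
        # Stratified folds.
        folds = np.empty(len(labels), dtype=int)
        for c in (0, 1):
            idx = np.flatnonzero(labels == c)
            rng.shuffle(idx)
            folds[idx] = np.arange(len(idx)) % n_folds
        self.folds = folds
        self.n_folds = n_folds
        self._stats = []
        for f in range(n_folds):
            train = folds != f
            stats = {}
            for c in (0, 1):
                Xc = features[train & (labels == c)]
                stats[c] = (len(Xc), Xc.sum(axis=0), Xc.T @ Xc)
            self._stats.append(stats)

    def score(self, subset: Sequence[int]) -> float:
        sub = np.asarray(subset, dtype=int)
        accs = np.zeros(2)
        for f in range(self.n_folds):
            stats = self._stats[f]
            mu = np.empty((2, len(sub)))
            S = np.zeros((len(sub), len(sub)))
            n_tot = 0
            for c in (0, 1):
                n, s, G = stats[c]
                mu[c] = s[sub] / n
                S += G[np.ix_(sub, sub)] - np.outer(mu[c], mu[c]) * n
                n_tot += n
            cov = S / max(n_tot - 2, 1)
            p = cov.shape[0]
            shrunk = (1 - self.gamma) * cov + self.gamma * (
                np.trace(cov) / p) * np.eye(p)
            try:
                w = np.linalg.solve(shrunk, mu[1] - mu[0])
            except np.linalg.LinAlgError:
                return 0.0
            b = -0.5 * w @ (mu[0] + mu[1])
            test = self.folds == f
            pred = (self.X[np.ix_(test, sub)] @ w + b >= 0).astype(int)
            yt = self.y[test]
            for c in (0, 1):
                accs[c] += np.mean(pred[yt == c] == c)
        return float(0.5 * accs.sum() / self.n_folds)


def stepwise_select_and_fit(features: np.ndarray, labels: Sequence[int],
                            config: StepwiseConfig = StepwiseConfig()
                            ) -> ClassifierModel:
    """Forward-backward stepwise feature selection with an RLDA scorer.

    Starting from an empty model, alternate (i) adding the candidate that most
    improves the cross-validated weighted accuracy, provided the improvement
    exceeds ``epsilon``, and (ii) removing any included feature whose removal
    does not cost more than ``epsilon``; stop when neither step changes the
    set.  Ties break toward the lowest feature id.  Returns the RLDA refit on
    the final subset (Ledoit-Wolf shrinkage on that subset unless a gamma is
    configured).
    """
    features = np.asarray(features, dtype=float)
    labels = _check_two_class(np.asarray(labels))
    for c in (0, 1):
        if np.sum(labels == c) < 20:
            raise ValueError("need at least 20 observations per class")

    if config.gamma is not None:
        gamma = config.gamma
    else:
        gamma = float(ledoit_wolf_shrinkage(features, assume_centered=False))
    scorer = _FoldScorer(features, labels, config.cv_folds, config.seed, gamma)

    selected: list[int] = []
    n_candidates = features.shape[1]
    current = 0.5  # chance-level weighted accuracy of the empty model
    changed = True
    iterations = 0
    while changed and iterations < 2 * config.max_features:
        iterations += 1
        changed = False
        # Forward: add the best-scoring candidate if it improves by > epsilon.
        if len(selected) < config.max_features:
            best_id, best_score = -1, -np.inf
            for j in range(n_candidates):
                if j in selected:
                    continue
                s = scorer.score(selected + [j])
                if s > best_score:  # ties keep the lowest feature id
                    best_id, best_score = j, s
            if best_id != -1 and best_score > current + config.epsilon:
                selected.append(best_id)
                current = best_score
                changed = True
        # Backward: drop a feature whose removal costs no more than epsilon.
        if len(selected) > 1:
            for j in sorted(selected):
                trial = [k for k in selected if k != j]
                s = scorer.score(trial)
                if s >= current - config.epsilon:
                    selected = trial
                    current = s
                    changed = True
                    break

    if not selected:
        raise ValueError("no informative features: nothing improves over the "
                         "empty model")
    model = fit_rlda(features[:, selected], labels,
                     gamma=config.gamma, selected=selected)
    return model
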