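"""Offline and online performance evaluation.

Offline: stratified five-fold cross-validation of the stepwise+RLDA stage
with per-class and weighted accuracies, and a label-permutation test of the
weighted accuracy.  Online: selection accuracy, Wolpaw-style bits per
selection

    B = log2(n_c) + acc*log2(acc) + (1-acc)*log2((1-acc)/(n_c-1)),

and the information transfer rate ITR = 60*B/t_avg (bit/min), plus paired
t / rank-sum comparisons between experimental conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .classification import StepwiseConfig, decision_scores, fit_rlda, \
    stepwise_select_and_fit
from .controller import AttemptResult

__all__ = [
    "CvReport",
    "PermutationReport",
    "OnlineReport",
    "crossval",
    "permutation_test",
    "itr",
    "online_report",
    "compare_conditions",
]


@dataclass(frozen=True)
class CvReport:
    """Cross-validated per-class and weighted accuracies (percent)."""

    acc_target: float
    acc_nontarget: float
    acc_weighted: float
    per_fold: tuple[tuple[float, float], ...]
    n_folds: int
    seed: int


@dataclass(frozen=True)
class PermutationReport:
    """Permutation test of the cross-validated weighted accuracy."""

    observed: float
    m: int
    p_value: float
    permuted: tuple[float, ...] = ()


@dataclass(frozen=True)
class OnlineReport:
    """Online selection performance: accuracy, timing, bits, ITR."""

    n_att: int
    n_sel: int
    acc_online: float      # percent
    t_avg: float | None    # s; None when no attempt succeeded
    bits: float
    itr: float             # bit/min; 0 when t_avg is undefined
    n_c: int
    condition_tag: str | None = None


def _stratified_folds(labels: np.ndarray, k: int,
                      rng: np.random.Generator) -> np.ndarray:
    folds = np.empty(len(labels), dtype=int)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < k:
            raise ValueError(f"class {c} has {len(idx)} members; need >= {k}")
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


def crossval(features: np.ndarray, labels: Sequence[int], k: int = 5,
             seed: int = 0, stepwise_config: StepwiseConfig | None = None,
             method: str = "stepwise") -> CvReport:
    """Stratified k-fold cross-validation of the classification stage.

    ``method='stepwise'`` re-runs the full stepwise selection + RLDA fit in
    every training fold (the evaluation the study design calls for);
    ``method='rlda'`` fits the RLDA on all supplied features, for quick
    scoring of small fixtures.  Per-class accuracies are pooled over the
    held-out folds; the weighted accuracy is their unweighted mean.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, k, rng)

    correct = np.zeros(2)
    totals = np.zeros(2)
    per_fold = []
    for f in range(k):
        train, test = folds != f, folds == f
        if method == "stepwise":
            cfg = stepwise_config or StepwiseConfig()
            try:
                model = stepwise_select_and_fit(X[train], y[train], cfg)
                scores = decision_scores(X[test], model, full_grid=True)
            except ValueError as exc:
                if "no informative features" not in str(exc):
                    raise
                # Empty model: no feature beats chance in this fold, so score
                # it as the constant non-target predictor.
                scores = np.full(int(np.sum(test)), -1.0)
        elif method == "rlda":
            model = fit_rlda(X[train], y[train])
            scores = decision_scores(X[test], model)
        else:
            raise ValueError(f"unknown method {method!r}")
        pred = (scores >= 0).astype(int)
        fold_acc = []
        for c in (0, 1):
            mask = y[test] == c
            correct[c] += np.sum(pred[mask] == c)
            totals[c] += np.sum(mask)
            fold_acc.append(100.0 * np.mean(pred[mask] == c))
        per_fold.append((fold_acc[1], fold_acc[0]))  # (target, non-target)

    acc_nt, acc_t = 100.0 * correct / totals
    return CvReport(acc_target=float(acc_t), acc_nontarget=float(acc_nt),
                    acc_weighted=0.5 * float(acc_t + acc_nt),
                    per_fold=tuple(per_fold), n_folds=k, seed=seed)


def permutation_test(features: np.ndarray, labels: Sequence[int],
                     m: int = 1000, seed: int = 0, k: int = 5,
                     method: str = "stepwise",
                     stepwise_config: StepwiseConfig | None = None,
                     keep_permuted: bool = False) -> PermutationReport:
    """Label-permutation test of the cross-validated weighted accuracy.

    Under the null the class labels are exchangeable, so each of the ``m``
    random label permutations is re-scored with the same cross-validation;
    the p-value uses the +1-smoothed estimator
    p = (1 + #{permuted >= observed}) / (1 + m), which is never zero.
    """
    if m < 1:
        raise ValueError("m must be positive")
    y = np.asarray(labels).astype(int)
    observed = crossval(features, y, k=k, seed=seed, method=method,
                        stepwise_config=stepwise_config).acc_weighted
    rng = np.random.default_rng(seed)
    permuted = []
    for _ in range(m):
        perm = rng.permutation(y)
        permuted.append(crossval(features, perm, k=k, seed=seed, method=method,
                                 stepwise_config=stepwise_config).acc_weighted)
    permuted_arr = np.asarray(permuted)
    p = (1 + int(np.sum(permuted_arr >= observed))) / (1 + m)
    return PermutationReport(observed=observed, m=m, p_value=float(p),
                             permuted=tuple(permuted) if keep_permuted else ())


def itr(acc: float, n_c: int = 6, t_avg: float = 1.0) -> tuple[float, float]:
    """Bits per selection and information transfer rate (bit/min).

    ``acc`` is the selection accuracy as a fraction.  Boundary conventions:
    the acc*log2(acc) term is 0 at acc = 0 and the (1-acc) term is 0 at
    acc = 1 (the 0*log2(0) = 0 limit).
    """
    if not 0.0 <= acc <= 1.0:
        raise ValueError("acc must lie in [0, 1]")
    if n_c < 2:
        raise ValueError("need at least two options")
    if t_avg <= 0:
        raise ValueError("t_avg must be positive")
    bits = float(np.log2(n_c))
    if acc > 0:
        bits += acc * float(np.log2(acc))
    if acc < 1:
        bits += (1 - acc) * float(np.log2((1 - acc) / (n_c - 1)))
    return bits, 60.0 * bits / t_avg


def online_report(attempts: Sequence[AttemptResult],
                  cued_targets: Sequence[int], n_c: int = 6,
                  condition_tag: str | None = None) -> OnlineReport:
    """Aggregate online attempts into accuracy, mean selection time, and ITR.

    A correct selection is one matching the cue; timeouts and wrong
    selections both count as failures.  ``t_avg`` averages the selection
    times of successful attempts only (a timeout has no selection time); when
    every attempt failed, ``t_avg`` is None and the ITR is reported as 0.
    """
    if len(attempts) == 0:
        raise ValueError("need at least one attempt")
    if len(attempts) != len(cued_targets):
        raise ValueError("attempts and cued_targets must align")
    n_att = len(attempts)
    correct_times = [a.selection_time_s for a, cue in zip(attempts, cued_targets)
                     if a.is_correct(cue)]
    n_sel = len(correct_times)
    acc = n_sel / n_att
    bits, _ = itr(acc, n_c, 1.0)
    if correct_times:
        t_avg: float | None = float(np.mean(correct_times))
        rate = 60.0 * bits / t_avg
    else:
        t_avg, rate = None, 0.0
    return OnlineReport(n_att=n_att, n_sel=n_sel, acc_online=100.0 * acc,
                        t_avg=t_avg, bits=bits, itr=rate, n_c=n_c,
                        condition_tag=condition_tag)


def compare_conditions(values_a: Sequence[float], values_b: Sequence[float],
                       method: str = "paired_t") -> tuple[float, float, dict]:
    """Two-sided comparison of paired (or independent) condition samples.

    ``paired_t`` runs the paired t-test (requires equal lengths, pairwise
    correspondence; reports df = n - 1); ``ranksum`` the Wilcoxon rank-sum
    test.  Returns (statistic, p_value, extras).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if method == "paired_t":
        if a.shape != b.shape:
            raise ValueError("paired_t needs equally long, aligned samples")
        if len(a) < 3:
            raise ValueError("need at least three pairs")
        if np.all(a == b):
            # Zero difference with zero spread: no evidence of any effect.
            return 0.0, 1.0, {"df": len(a) - 1}
        res = stats.ttest_rel(a, b)
        return float(res.statistic), float(res.pvalue), {"df": len(a) - 1}
    if method == "ranksum":
        if min(len(a), len(b)) < 3:
            raise ValueError("need at least three observations per group")
        res = stats.ranksums(a, b)
        return float(res.statistic), float(res.pvalue), {}
    raise ValueError(f"unknown method {method!r}")
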