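"""Model evaluation: ROC/AUC, k-fold cross-validation, out-of-bag bootstrap,
coefficient aggregation and country ranking.

Predictive performance of a per-variant model measures the strength of the
origin-variant association: AUC 0.5 is a random prediction, 1.0 a perfect
one.  Two resampling schemes are provided:

* **k-fold cross-validation** (default k = 10): rows are partitioned at
  random (unstratified) into k folds; each fold is scored by a model trained
  on the rest.
* **out-of-bag bootstrap** (default B = 1000): each replicate trains on n
  rows drawn with replacement and is scored on the rows left out of the
  draw (about 36.8% of the data for large n).

Resamples whose test part is degenerate (empty, or single-class on either
side) are skipped and counted rather than aborting the run.  The coefficient
vectors of the successful resample fits are averaged; countries sorted by
that mean coefficient give the ranking used to pick the most and least
associated origins (the sex feature never enters the ranking; ties break
lexicographically).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .logistic_model import INTERCEPT, SEX_FEATURE, FeatureTable, FitResult, fit_logistic, predict_proba

__all__ = [
    "EvaluationReport",
    "CountryRanking",
    "auc",
    "roc_curve",
    "kfold_evaluate",
    "bootstrap_evaluate",
    "rank_countries",
]


def _check_two_class(labels: np.ndarray) -> tuple[np.ndarray, int, int]:
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    return y, n_pos, n_neg


def auc(scores, labels) -> float:
    """Tie-adjusted area under the ROC curve.

    Equals the Mann-Whitney probability P(score+ > score-) + 0.5 P(tie),
    computed from midranks.
    """
    s = np.asarray(scores, dtype=float)
    y, n_pos, n_neg = _check_two_class(labels)
    ranks = rankdata(s)  # midranks handle ties
    rank_sum_pos = float(ranks[y == 1].sum())
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def roc_curve(scores, labels) -> np.ndarray:
    """Ordered ROC points as an (m, 2) array of (FPR, TPR).

    Thresholds sweep the distinct score values from high to low; the curve
    starts at (0, 0), ends at (1, 1), and its trapezoidal area equals
    :func:`auc` (ties contribute diagonal segments).
    """
    s = np.asarray(scores, dtype=float)
    y, n_pos, n_neg = _check_two_class(labels)
    order = np.argsort(-s, kind="mergesort")
    s, y = s[order], y[order]
    tps = np.cumsum(y == 1)
    fps = np.cumsum(y == 0)
    # keep only the last index of each tied-score run
    last = np.r_[s[1:] != s[:-1], True]
    points = np.column_stack([fps[last] / n_neg, tps[last] / n_pos])
    return np.vstack([[0.0, 0.0], points])


@dataclass(frozen=True)
class EvaluationReport:
    """Resampling evaluation of one per-variant model."""

    scheme: str  # "kfold" or "bootstrap"
    params: dict
    seed: int
    aucs: tuple[float, ...]  # one AUC per successful resample
    skipped: int  # degenerate resamples (empty / single-class test part)
    coef: pd.DataFrame  # successful-resample coefficient vectors (incl. intercept)
    pooled_scores: np.ndarray  # test-part scores concatenated across resamples
    pooled_labels: np.ndarray

    @property
    def n_resamples(self) -> int:
        return len(self.aucs) + self.skipped

    @property
    def mean_auc(self) -> float:
        if not self.aucs:
            raise ValueError("no successful resamples")
        return float(np.mean(self.aucs))

    @property
    def coef_mean(self) -> pd.Series:
        """Coefficient vector averaged over successful resamples."""
        if self.coef.empty:
            raise ValueError("no successful resamples")
        return self.coef.mean(axis=0)

    def pooled_roc(self) -> np.ndarray:
        return roc_curve(self.pooled_scores, self.pooled_labels)


def _evaluate_split(
    table: FeatureTable,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    fit_kwargs: dict,
) -> tuple[FitResult, float, np.ndarray] | None:
    """Fit on the training rows, score the test rows.

    Returns None (a skip) when either part is single-class or the test part
    is empty.
    """
    if len(test_idx) == 0:
        return None
    y_train = table.labels[train_idx]
    y_test = table.labels[test_idx]
    if np.unique(y_train).size < 2 or np.unique(y_test).size < 2:
        return None
    fit = fit_logistic(table.take(train_idx), **fit_kwargs)
    scores = predict_proba(fit, table.features.iloc[test_idx])
    return fit, auc(scores, y_test), scores


def _collect(
    table: FeatureTable,
    splits,
    scheme: str,
    params: dict,
    seed: int,
    fit_kwargs: dict,
) -> EvaluationReport:
    aucs: list[float] = []
    coef_rows: list[pd.Series] = []
    pooled_s: list[np.ndarray] = []
    pooled_y: list[np.ndarray] = []
    skipped = 0
    for train_idx, test_idx in splits:
        out = _evaluate_split(table, train_idx, test_idx, fit_kwargs)
        if out is None:
            skipped += 1
            continue
        fit, fold_auc, scores = out
        aucs.append(fold_auc)
        coef_rows.append(fit.as_series())
        pooled_s.append(scores)
        pooled_y.append(table.labels[test_idx])
    coef = (
        pd.DataFrame(coef_rows).reset_index(drop=True)
        if coef_rows
        else pd.DataFrame(columns=[INTERCEPT, *table.features.columns])
    )
    return EvaluationReport(
        scheme=scheme,
        params=params,
        seed=seed,
        aucs=tuple(aucs),
        skipped=skipped,
        coef=coef,
        pooled_scores=np.concatenate(pooled_s) if pooled_s else np.empty(0),
        pooled_labels=np.concatenate(pooled_y) if pooled_y else np.empty(0),
    )


def kfold_evaluate(
    table: FeatureTable,
    k: int = 10,
    seed: int = 0,
    stratified: bool = False,
    **fit_kwargs,
) -> EvaluationReport:
    """k-fold cross-validation (plain random folds by default).

    Rows are permuted by the seeded generator and split into k folds whose
    sizes differ by at most one.  ``stratified=True`` permutes within each
    class instead, keeping fold class ratios near the overall ratio.
    Additional keyword arguments are passed to the logistic fit.
    """
    n = table.n
    if n < k:
        raise ValueError(f"need at least k={k} rows, got {n}")
    rng = np.random.default_rng(seed)
    if stratified:
        order = np.empty(n, dtype=int)
        pos = 0
        for cls in (0, 1):
            idx = np.flatnonzero(table.labels == cls)
            order[pos : pos + idx.size] = rng.permutation(idx)
            pos += idx.size
        folds = [order[i::k] for i in range(k)]
    else:
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
    all_idx = np.arange(n)
    splits = [
        (np.setdiff1d(all_idx, fold, assume_unique=False), np.sort(fold))
        for fold in folds
    ]
    return _collect(
        table, splits, "kfold", {"k": k, "stratified": stratified}, seed, fit_kwargs
    )


def bootstrap_evaluate(
    table: FeatureTable,
    B: int = 1000,
    seed: int = 0,
    **fit_kwargs,
) -> EvaluationReport:
    """Out-of-bag bootstrap: train on n rows drawn with replacement, test on
    the rows the draw missed.  Replicates with a degenerate out-of-bag set
    are skipped and counted."""
    n = table.n
    if n < 10:
        raise ValueError(f"bootstrap evaluation needs at least 10 rows, got {n}")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(B):
        bag = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), bag)
        splits.append((bag, oob))
    return _collect(table, splits, "bootstrap", {"B": B}, seed, fit_kwargs)


@dataclass(frozen=True)
class CountryRanking:
    """Countries ordered by mean coefficient, most positively associated
    first.  Ties break lexicographically on the country code."""

    entries: tuple[tuple[str, float], ...]

    def top(self, size: int = 4) -> tuple[str, ...]:
        """The ``size`` most positively associated countries, strongest first."""
        self._check(size)
        return tuple(c for c, _ in self.entries[:size])

    def bottom(self, size: int = 4) -> tuple[str, ...]:
        """The ``size`` most negatively associated countries, strongest
        (most negative) first."""
        self._check(size)
        return tuple(c for c, _ in self.entries[::-1][:size])

    def _check(self, size: int) -> None:
        if size > len(self.entries):
            raise ValueError(
                f"ranking has {len(self.entries)} countries, cannot take {size}"
            )

    def to_series(self) -> pd.Series:
        return pd.Series(dict(self.entries), name="mean_coefficient")


def rank_countries(
    report: EvaluationReport,
    exclude: tuple[str, ...] = (INTERCEPT, SEX_FEATURE),
) -> CountryRanking:
    """Rank country features by their mean coefficient across successful
    resamples (descending); the intercept and sex never enter the ranking."""
    if report.coef.empty:
        raise ValueError("no successful resamples to rank from")
    means = report.coef_mean.drop(labels=[c for c in exclude if c in report.coef_mean.index])
    ordered = sorted(means.items(), key=lambda kv: (-kv[1], kv[0]))
    return CountryRanking(tuple(ordered))
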