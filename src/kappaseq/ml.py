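"""Random-forest models of Vk gene activity and rearrangement frequency.

Supervised analyses over the gene x feature matrix: a classifier for
active vs inactive genes and regressors for recombination frequency and
RNA/gDNA ratio.  Evaluation is 10-fold cross-validation with every gene in
a test set exactly once and 5,000 trees per fold by default; variable
importance (VI) is impurity-based -- mean decrease in Gini index for
classification, mean decrease in node purity for regression -- averaged
over folds.  Feature selection restricts to the top-20 VI features and
runs recursive feature elimination over VI-ranked nested subsets, scoring
each subset size by cross-validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import KFold

DEFAULT_N_TREES = 5000
DEFAULT_N_FOLDS = 10


@dataclass
class ModelReport:
    task: str                    # classification | regression
    response: str
    performance: float           # accuracy or RMSE across pooled test sets
    performance_metric: str      # accuracy | rmse
    vi: pd.Series                # per-feature importance, fold-averaged
    n_trees: int
    n_folds: int
    seed: int
    predictions: pd.Series = field(default_factory=pd.Series)
    mtry_per_fold: list[int] = field(default_factory=list)
    rfe: Optional[pd.DataFrame] = None
    rfe_selected: Optional[list[str]] = None


def _folds(n: int, n_folds: int, seed: int):
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(kf.split(np.arange(n)))


def _check_cv(n: int, splits) -> None:
    seen = np.concatenate([test for _, test in splits])
    assert len(seen) == n and len(np.unique(seen)) == n, "invalid CV partition"


def rf_classify(
    matrix: pd.DataFrame,
    labels: pd.Series,
    n_trees: int = DEFAULT_N_TREES,
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int = 0,
    tune_mtry: bool = True,
) -> ModelReport:
    """Cross-validated random-forest classification of gene activity.

    The per-split candidate count (mtry) is tuned on each training fold
    only, by out-of-bag score over {sqrt(p)/2, sqrt(p), 2*sqrt(p)};
    accuracy is the fraction of correct predictions pooled over all test
    sets; VI is mean decrease in Gini index averaged over folds.
    """
    y = labels.reindex(matrix.index)
    classes = y.unique()
    if len(classes) < 2:
        raise ValueError("classification requires both classes present")
    X = matrix.to_numpy(dtype=float)
    yv = y.to_numpy()
    n, p = X.shape
    splits = _folds(n, n_folds, seed)
    _check_cv(n, splits)
    base = max(int(round(math.sqrt(p))), 1)
    grid = sorted({max(base // 2, 1), base, min(2 * base, p)})

    preds = np.empty(n, dtype=object)
    vi_folds = []
    mtry_used = []
    for fi, (train, test) in enumerate(splits):
        mtry = base
        if tune_mtry and len(grid) > 1:
            best = -np.inf
            for m in grid:
                probe = RandomForestClassifier(
                    n_estimators=max(n_trees // 10, 50), max_features=m,
                    oob_score=True, bootstrap=True,
                    random_state=seed * 1000 + fi, n_jobs=1,
                )
                probe.fit(X[train], yv[train])
                if probe.oob_score_ > best:
                    best, mtry = probe.oob_score_, m
        clf = RandomForestClassifier(
            n_estimators=n_trees, max_features=mtry,
            random_state=seed * 1000 + fi, n_jobs=1,
        )
        clf.fit(X[train], yv[train])
        preds[test] = clf.predict(X[test])
        vi_folds.append(clf.feature_importances_)
        mtry_used.append(mtry)
    accuracy = float((preds == yv).mean())
    vi = pd.Series(np.mean(vi_folds, axis=0), index=matrix.columns,
                   name="mean_decrease_gini").sort_values(ascending=False)
    return ModelReport(
        task="classification", response="activity", performance=accuracy,
        performance_metric="accuracy", vi=vi, n_trees=n_trees,
        n_folds=n_folds, seed=seed,
        predictions=pd.Series(preds, index=matrix.index),
        mtry_per_fold=mtry_used,
    )


def rf_regress(
    matrix: pd.DataFrame,
    response: pd.Series,
    response_name: str = "recombination_frequency",
    n_trees: int = DEFAULT_N_TREES,
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int = 0,
    min_observations: int = 20,
) -> ModelReport:
    """Cross-validated random-forest regression (default mtry = p/3, the
    regression default); performance is RMSE over pooled test predictions;
    VI is mean decrease in node purity averaged over folds."""
    y = response.reindex(matrix.index)
    if y.isna().any():
        raise ValueError("response missing for some genes")
    if len(y) < min_observations:
        raise ValueError(
            f"too few observations for regression ({len(y)} < {min_observations})")
    X = matrix.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    n, p = X.shape
    splits = _folds(n, n_folds, seed)
    _check_cv(n, splits)
    mtry = max(p // 3, 1)
    preds = np.empty(n, dtype=float)
    vi_folds = []
    for fi, (train, test) in enumerate(splits):
        reg = RandomForestRegressor(
            n_estimators=n_trees, max_features=mtry,
            random_state=seed * 1000 + fi, n_jobs=1,
        )
        reg.fit(X[train], yv[train])
        preds[test] = reg.predict(X[test])
        vi_folds.append(reg.feature_importances_)
    rmse = float(np.sqrt(np.mean((preds - yv) ** 2)))
    vi = pd.Series(np.mean(vi_folds, axis=0), index=matrix.columns,
                   name="mean_decrease_node_purity").sort_values(ascending=False)
    return ModelReport(
        task="regression", response=response_name, performance=rmse,
        performance_metric="rmse", vi=vi, n_trees=n_trees, n_folds=n_folds,
        seed=seed, predictions=pd.Series(preds, index=matrix.index),
    )


def _cv_score(X, y, task, n_trees, n_folds, seed) -> tuple[float, float]:
    """(mean, SE) of per-fold performance; accuracy for classification,
    negative RMSE for regression (higher is better for both)."""
    splits = _folds(len(y), n_folds, seed)
    scores = []
    for fi, (train, test) in enumerate(splits):
        if task == "classification":
            m = RandomForestClassifier(n_estimators=n_trees,
                                       random_state=seed * 1000 + fi, n_jobs=1)
            m.fit(X[train], y[train])
            scores.append(float((m.predict(X[test]) == y[test]).mean()))
        else:
            m = RandomForestRegressor(n_estimators=n_trees,
                                      max_features=max(X.shape[1] // 3, 1),
                                      random_state=seed * 1000 + fi, n_jobs=1)
            m.fit(X[train], y[train])
            scores.append(-float(np.sqrt(np.mean((m.predict(X[test]) - y[test]) ** 2))))
    scores = np.asarray(scores)
    return float(scores.mean()), float(scores.std(ddof=1) / np.sqrt(len(scores)))


def rfe_select(
    matrix: pd.DataFrame,
    response: pd.Series,
    initial_report: ModelReport,
    top_k: int = 20,
    sizes: Optional[Sequence[int]] = None,
    n_trees: Optional[int] = None,
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Recursive feature elimination over VI-ranked nested subsets of the
    top-``top_k`` features from an initial model.

    Returns the performance-vs-size curve and the smallest subset whose
    cross-validated performance is within one standard error of the best.
    """
    task = initial_report.task
    if top_k > matrix.shape[1]:
        top_k = matrix.shape[1]
    ranked = initial_report.vi.index[:top_k].tolist()
    if sizes is None:
        sizes = list(range(1, top_k + 1))
    sizes = sorted({min(s, top_k) for s in sizes})
    n_trees = n_trees or initial_report.n_trees
    y = response.reindex(matrix.index).to_numpy()
    rows = []
    for s in sizes:
        feats = ranked[:s]
        mean, se = _cv_score(matrix[feats].to_numpy(dtype=float), y, task,
                             n_trees, n_folds, seed)
        rows.append({"n_features": s, "score": mean, "se": se})
    curve = pd.DataFrame(rows)
    best = curve.loc[curve["score"].idxmax()]
    ok = curve[curve["score"] >= best["score"] - best["se"]]
    chosen_size = int(ok["n_features"].min())
    selected = ranked[:chosen_size]
    return curve, selected


def correlate_feature(
    matrix: pd.DataFrame,
    response: pd.Series,
    feature: str,
) -> tuple[float, float]:
    """Pearson r and two-sided p between one feature and the response."""
    x = matrix[feature].reindex(response.index).to_numpy(dtype=float)
    y = response.to_numpy(dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
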