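"""Nearest shrunken centroid classification with nested cross-validation.

Implements the soft-thresholded centroid classifier: standardized class-vs-
overall centroid differences are shrunk toward zero by a threshold delta,
features whose differences vanish for every class drop out, and samples are
assigned to the class minimizing the standardized distance to its shrunken
centroid penalized by the log prior. Nested CV picks delta on inner folds
(ties toward more shrinkage) and aggregates outer-fold predictions into an
unbiased confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .io import ExpressionMatrix

__all__ = [
    "CentroidModel",
    "pam_fit",
    "pam_predict",
    "nested_cv",
    "per_class_error",
]


@dataclass(eq=False)
class CentroidModel:
    classes: list
    features: list[str]
    shrunken_centroids: np.ndarray  # (K, G)
    overall_centroid: np.ndarray  # (G,)
    s: np.ndarray  # pooled within-class SD per feature
    s0: float
    delta: float
    priors: np.ndarray  # (K,)
    surviving: np.ndarray  # bool (G,): nonzero shrunken difference in any class
    d_max: float = 0.0  # largest |d_kg| before shrinkage

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")

    @property
    def surviving_features(self) -> list[str]:
        return [f for f, keep in zip(self.features, self.surviving) if keep]


def _as_df(matrix) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, ExpressionMatrix) else matrix


def pam_fit(matrix, labels, delta: float = 0.0) -> CentroidModel:
    """Fit shrunken centroids at threshold ``delta``.

    ``d_kg = (xbar_kg - xbar_g) / (m_k (s_g + s0))`` with
    ``m_k = sqrt(1/n_k - 1/n)`` is soft-thresholded:
    ``d'_kg = sign(d_kg) max(0, |d_kg| - delta)``, and centroids are
    reconstructed as ``xbar_g + m_k (s_g + s0) d'_kg``.
    """
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    df = _as_df(matrix)
    y = pd.Series(labels, index=df.columns) if not isinstance(labels, pd.Series) else labels
    y = y.reindex(df.columns)
    if y.isna().any():
        raise ValueError("labels missing for some samples")
    classes = sorted(pd.unique(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    X = df.to_numpy(dtype=float)  # (G, n)
    G, n = X.shape
    counts = np.array([(y == c).sum() for c in classes])
    if (counts < 2).any():
        small = classes[int(np.argmin(counts))]
        raise ValueError(f"class {small!r} has fewer than 2 samples")
    overall = X.mean(axis=1)
    cent = np.stack([X[:, (y == c).to_numpy()].mean(axis=1) for c in classes])
    within_ss = np.zeros(G)
    for k, c in enumerate(classes):
        Xi = X[:, (y == c).to_numpy()]
        within_ss += ((Xi - cent[k][:, None]) ** 2).sum(axis=1)
    s = np.sqrt(within_ss / (n - len(classes)))
    s0 = float(np.median(s))
    mk = np.sqrt(1.0 / counts - 1.0 / n)  # (K,)
    denom = mk[:, None] * (s + s0)[None, :]
    d = (cent - overall[None, :]) / denom
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    shrunken = overall[None, :] + denom * d_shrunk
    surviving = (d_shrunk != 0).any(axis=0)
    return CentroidModel(
        classes=list(classes),
        features=list(df.index),
        shrunken_centroids=shrunken,
        overall_centroid=overall,
        s=s,
        s0=s0,
        delta=float(delta),
        priors=counts / n,
        surviving=surviving,
        d_max=float(np.abs(d).max()),
    )


def pam_predict(model: CentroidModel, matrix):
    """Predict class labels and per-class discriminant scores.

    Discriminant: ``sum_g (x_g - centroid_kg)^2 / (s_g + s0)^2 - 2 log pi_k``;
    the minimizing class wins, ties going to the lexicographically first
    class. Features must match the model exactly.
    """
    df = _as_df(matrix)
    if list(df.index) != model.features:
        raise ValueError("prediction features do not match the fitted model")
    X = df.to_numpy(dtype=float)
    w = 1.0 / (model.s + model.s0) ** 2
    scores = np.stack(
        [
            (w[:, None] * (X - model.shrunken_centroids[k][:, None]) ** 2).sum(axis=0)
            - 2.0 * np.log(model.priors[k])
            for k in range(len(model.classes))
        ]
    )  # (K, n)
    # argmin with lexicographic tie-break: classes are sorted, argmin takes
    # the first minimum
    pred_idx = np.argmin(scores, axis=0)
    labels = pd.Series([model.classes[i] for i in pred_idx], index=df.columns)
    score_df = pd.DataFrame(scores.T, index=df.columns, columns=model.classes)
    return labels, score_df


def _delta_grid(matrix, labels, n_points: int) -> np.ndarray:
    base = pam_fit(matrix, labels, delta=0.0)
    return np.linspace(0.0, base.d_max, n_points)


def nested_cv(matrix, labels, outer_k: int = 10, inner_k: int = 5,
              n_delta: int = 30, seed: int = 0):
    """Nested cross-validated shrunken-centroid classification.

    Inner CV (on each outer training part) picks the delta minimizing the
    inner misclassification count, ties resolved toward the *larger* delta;
    outer-fold test predictions are pooled into one confusion matrix.
    Returns ``(confusion, per_class_errors, consensus_features)`` where the
    consensus is the intersection of surviving features across all outer-fold
    models.
    """
    if outer_k < 2 or inner_k < 2:
        raise ValueError("outer_k and inner_k must be >= 2")
    df = _as_df(matrix)
    y = pd.Series(labels, index=df.columns) if not isinstance(labels, pd.Series) else labels
    y = y.reindex(df.columns)
    if y.isna().any():
        raise ValueError("labels missing for some samples")
    classes = sorted(pd.unique(y))
    counts = y.value_counts()
    if (counts < outer_k).any():
        small = counts.idxmin()
        raise ValueError(
            f"class {small!r} has {counts.min()} samples, fewer than outer_k={outer_k}"
        )
    y_arr = y.to_numpy()
    cols = np.array(df.columns)
    outer = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=seed)
    confusion = pd.DataFrame(0, index=classes, columns=classes)
    consensus: set[str] | None = None
    for fold, (tr, te) in enumerate(outer.split(cols, y_arr)):
        df_tr = df.iloc[:, tr]
        y_tr = y.iloc[tr]
        grid = _delta_grid(df_tr, y_tr, n_delta)
        inner = StratifiedKFold(n_splits=inner_k, shuffle=True,
                                random_state=seed + 1000 + fold)
        errors = np.zeros(grid.size)
        for itr, ite in inner.split(np.arange(len(tr)), y_tr.to_numpy()):
            df_itr = df_tr.iloc[:, itr]
            y_itr = y_tr.iloc[itr]
            df_ite = df_tr.iloc[:, ite]
            y_ite = y_tr.iloc[ite].to_numpy()
            for j, delta in enumerate(grid):
                mdl = pam_fit(df_itr, y_itr, delta=delta)
                pred, _ = pam_predict(mdl, df_ite)
                errors[j] += int((pred.to_numpy() != y_ite).sum())
        # ties toward larger delta (more shrinkage)
        best_delta = grid[errors.size - 1 - int(np.argmin(errors[::-1]))]
        mdl = pam_fit(df_tr, y_tr, delta=best_delta)
        surv = set(mdl.surviving_features)
        consensus = surv if consensus is None else (consensus & surv)
        pred, _ = pam_predict(mdl, df.iloc[:, te])
        for t_lab, p_lab in zip(y.iloc[te], pred):
            confusion.loc[t_lab, p_lab] += 1
    errors = per_class_error(confusion)
    return confusion, errors, sorted(consensus or set())


def per_class_error(confusion: pd.DataFrame) -> pd.Series:
    """Per-true-class error rate: off-diagonal row mass / row sum."""
    conf = confusion if isinstance(confusion, pd.DataFrame) else pd.DataFrame(confusion)
    arr = conf.to_numpy()
    if (arr < 0).any() or not np.issubdtype(np.asarray(arr).dtype, np.number):
        raise ValueError("confusion matrix must hold nonnegative counts")
    row_sums = arr.sum(axis=1)
    if (row_sums == 0).any():
        empty = conf.index[int(np.argmin(row_sums))]
        raise ValueError(f"empty true-class row: {empty!r}")
    diag = np.array([conf.iloc[i][conf.index[i]] if conf.index[i] in conf.columns else 0
                     for i in range(len(conf.index))], dtype=float)
    return pd.Series((row_sums - diag) / row_sums, index=conf.index)
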