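"""Normalization, duplicate-aware variance filtering, and the train/model-
selection sample partition."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix

__all__ = [
    "quantile_normalize",
    "vst_surrogate",
    "filter_variable_genes",
    "split_train_model_selection",
]


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean order-statistic distribution.

    Each sample's sorted values are replaced by the across-sample mean of
    order statistics; within-sample ranks are preserved and ties receive the
    mean of the values they would have occupied (average ranks).
    """
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in input")
    ref = np.sort(X, axis=0).mean(axis=1)  # mean order statistics
    g = X.shape[0]
    out = np.empty_like(X)
    grid = np.arange(g, dtype=float)
    for j in range(X.shape[1]):
        ranks = rankdata(X[:, j], method="average") - 1.0
        # average ranks land between integers for ties; linear interpolation
        # over the reference order statistics yields the mean of their values
        out[:, j] = np.interp(ranks, grid, ref)
    df = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(df, list(matrix.duplicate_pairs))


def vst_surrogate(matrix: ExpressionMatrix, raw_scale: bool = True) -> ExpressionMatrix:
    """Variance-stabilizing transform surrogate.

    ``log2(x + 1)`` for raw-scale (non-negative) intensities; identity when
    the data are declared already transformed. Monotone either way, so
    within-sample rank order is preserved.
    """
    if not raw_scale:
        return ExpressionMatrix(matrix.values.copy(), list(matrix.duplicate_pairs))
    X = matrix.values.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("negative values are incompatible with raw-scale VST")
    df = pd.DataFrame(
        np.log2(X + 1.0), index=matrix.values.index, columns=matrix.values.columns
    )
    return ExpressionMatrix(df, list(matrix.duplicate_pairs))


def duplicate_variability(matrix: ExpressionMatrix) -> pd.Series:
    """Per-gene mean absolute within-duplicate-pair difference."""
    if not matrix.duplicate_pairs:
        raise ValueError("matrix has no duplicate pairs")
    diffs = [
        (matrix.values[a] - matrix.values[b]).abs() for a, b in matrix.duplicate_pairs
    ]
    return pd.concat(diffs, axis=1).mean(axis=1)


def filter_variable_genes(matrix: ExpressionMatrix, k: int,
                          dup_quantile: float = 0.75) -> list[str]:
    """Select the ``k`` genes most variable across samples among those with
    low technical (within-duplicate-pair) variability.

    A gene is excluded when its mean absolute within-pair difference exceeds
    the ``dup_quantile`` quantile of that statistic across genes. Variance is
    computed over unique samples only (duplicate second copies dropped).
    Deterministic: ties in variance break by gene ID.
    """
    if k > matrix.shape[0]:
        raise ValueError(f"k={k} exceeds number of genes ({matrix.shape[0]})")
    if dup_quantile < 1.0 and not matrix.duplicate_pairs:
        raise ValueError("duplicate filtering requested but matrix has no duplicate pairs")

    if matrix.duplicate_pairs and dup_quantile < 1.0:
        stat = duplicate_variability(matrix)
        thr = stat.quantile(dup_quantile)
        survivors = stat.index[stat.to_numpy() <= thr]
    else:
        survivors = matrix.values.index

    copies = {b for _, b in matrix.duplicate_pairs}
    unique_cols = [c for c in matrix.values.columns if c not in copies]
    var = matrix.values.loc[survivors, unique_cols].var(axis=1, ddof=1)

    if k > len(survivors):
        raise ValueError(
            f"k={k} exceeds the {len(survivors)} genes surviving the duplicate filter"
        )
    order = pd.DataFrame({"var": var, "gene": var.index}).sort_values(
        ["var", "gene"], ascending=[False, True]
    )
    return list(order["gene"].iloc[:k])


def split_train_model_selection(samples, n_train: int, seed: int = 0,
                                duplicate_pairs=()) -> tuple[list[str], list[str]]:
    """Seeded disjoint partition of unique samples into training and
    model-selection sets; both members of a duplicate pair stay together.

    ``samples`` are the unique sample IDs (duplicate copies, if passed, are
    attached to their originals and do not count toward ``n_train``).
    """
    samples = list(samples)
    copy_of = {b: a for a, b in duplicate_pairs}
    units = [s for s in samples if s not in copy_of]
    attached: dict[str, list[str]] = {s: [s] for s in units}
    for b, a in copy_of.items():
        if a in attached and b in samples:
            attached[a].append(b)
    if n_train <= 1:
        raise ValueError("n_train must exceed 1")
    if n_train >= len(units):
        raise ValueError(f"n_train={n_train} must be below the {len(units)} unique samples")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(units))
    train_units, train_count = [], 0
    for u in order:
        if train_count < n_train:
            train_units.append(u)
            train_count += 1
    train_set = set(train_units)
    train = [s for s in samples if (copy_of.get(s, s)) in train_set]
    model = [s for s in samples if (copy_of.get(s, s)) not in train_set]
    return train, model
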