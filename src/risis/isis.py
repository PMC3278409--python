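"""Search for binary sample partitions supported by a compact gene module.

The search looks for bipartitions of the samples whose ``m`` most
discriminating genes (by moderated two-sample t-statistic) give a large mean
squared t — partitions "with clear separation". Candidate partitions are
seeded from 2-means splits on leading principal components and from
largest-gap threshold splits on highly variable genes, then hill-climbed by
single-sample reassignment. Significance is assessed against a
structure-destroying permutation null (each gene's values shuffled
independently across samples, the full search re-run, max refined score
recorded), which accounts for the selection bias of the search itself.

The split score is a surrogate separation statistic::

    t_g = (mean_g1 - mean_g0) / sqrt((sp2_g + s0) * (1/n1 + 1/n0))
    score = mean of the m largest t_g^2

with ``sp2_g`` the pooled within-class variance and ``s0`` a variance floor
(median of overall gene variances) that damps near-constant genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .io import ExpressionMatrix

__all__ = [
    "Bipartition",
    "DiscriminantModel",
    "split_score",
    "search_splits",
    "lda_train",
    "lda_predict",
    "label_agreement",
]

_EPS_IMPROVE = 1e-12


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _score_kernel(sum1, ss1, n1, tot_sum, tot_ss, n, s0, m, buf):
    """Mean of the m largest squared moderated t-statistics for the class
    assignment summarized by (sum1, ss1, n1). Returns -1 for infeasible
    class sizes."""
    n0 = n - n1
    if n1 < 2 or n0 < 2:
        return -1.0
    G = sum1.shape[0]
    inv = 1.0 / n1 + 1.0 / n0
    dof = n - 2
    for g in range(G):
        sum0 = tot_sum[g] - sum1[g]
        ss0 = tot_ss[g] - ss1[g]
        m1 = sum1[g] / n1
        m0 = sum0 / n0
        v1 = ss1[g] - n1 * m1 * m1
        v0 = ss0 - n0 * m0 * m0
        sp2 = (v1 + v0) / dof
        if sp2 < 0.0:
            sp2 = 0.0
        d = m1 - m0
        buf[g] = d * d / ((sp2 + s0) * inv)
    if m >= G:
        total = 0.0
        for g in range(G):
            total += buf[g]
        return total / G
    part = np.partition(buf, G - m)
    total = 0.0
    for g in range(G - m, G):
        total += part[g]
    return total / m


@njit(cache=True)
def _refine_kernel(X, labels, m, s0, min_size, max_sweeps):
    """Hill-climb ``labels`` in place by single-sample reassignment, sweeping
    samples in order and accepting any improving flip, until a full sweep
    changes nothing (or ``max_sweeps`` is hit). Returns the final score."""
    G, n = X.shape
    tot_sum = np.zeros(G)
    tot_ss = np.zeros(G)
    sum1 = np.zeros(G)
    ss1 = np.zeros(G)
    n1 = 0
    for s in range(n):
        in1 = labels[s] == 1
        if in1:
            n1 += 1
        for g in range(G):
            x = X[g, s]
            tot_sum[g] += x
            tot_ss[g] += x * x
            if in1:
                sum1[g] += x
                ss1[g] += x * x
    buf = np.empty(G)
    tmp_sum = np.empty(G)
    tmp_ss = np.empty(G)
    best = _score_kernel(sum1, ss1, n1, tot_sum, tot_ss, n, s0, m, buf)
    for _sweep in range(max_sweeps):
        changed = False
        for s in range(n):
            if labels[s] == 1:
                new_n1 = n1 - 1
                sign = -1.0
            else:
                new_n1 = n1 + 1
                sign = 1.0
            small = new_n1 if new_n1 < n - new_n1 else n - new_n1
            if small < min_size or new_n1 < 2 or n - new_n1 < 2:
                continue
            for g in range(G):
                x = X[g, s]
                tmp_sum[g] = sum1[g] + sign * x
                tmp_ss[g] = ss1[g] + sign * x * x
            sc = _score_kernel(tmp_sum, tmp_ss, new_n1, tot_sum, tot_ss, n, s0, m, buf)
            if sc > best + 1e-12:
                best = sc
                labels[s] = 1 - labels[s]
                n1 = new_n1
                for g in range(G):
                    sum1[g] = tmp_sum[g]
                    ss1[g] = tmp_ss[g]
                changed = True
        if not changed:
            break
    return best


# ---------------------------------------------------------------------------
# data containers


@dataclass(eq=False)
class Bipartition:
    """A binary sample partition; g1 is the smaller class (label 1)."""

    labels: pd.Series  # index: sample IDs; values 0/1
    module: list[str]
    t_stats: pd.Series  # per module gene
    score: float
    pvalue: float | None = None
    weights: pd.Series | None = None

    def __post_init__(self) -> None:
        n1 = int((self.labels == 1).sum())
        if n1 > len(self.labels) - n1:
            raise ValueError("g1 must be the smaller (or equal) class")
        if self.score < 0:
            raise ValueError("score must be nonnegative")

    @property
    def n_g1(self) -> int:
        return int((self.labels == 1).sum())

    def to_dict(self) -> dict:
        return {
            "labels": {s: int(v) for s, v in self.labels.items()},
            "module": list(self.module),
            "t_stats": {g: float(t) for g, t in self.t_stats.items()},
            "score": float(self.score),
            "pvalue": None if self.pvalue is None else float(self.pvalue),
            "weights": None
            if self.weights is None
            else {g: float(w) for g, w in self.weights.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Bipartition":
        return cls(
            labels=pd.Series(d["labels"]).astype(int),
            module=list(d["module"]),
            t_stats=pd.Series(d["t_stats"], dtype=float),
            score=float(d["score"]),
            pvalue=d.get("pvalue"),
            weights=None if d.get("weights") is None else pd.Series(d["weights"], dtype=float),
        )


@dataclass(eq=False)
class DiscriminantModel:
    """Diagonal linear discriminant over a gene module.

    ``w_g = (mean_g1 - mean_g0) / (s_g^2 + s0)`` with centers at class-mean
    midpoints; the projection ``sum_g w_g (x_g - center_g)`` is positive on
    the g1 side. ``threshold`` is set at the training equal-error point.
    """

    genes: list[str]
    weights: pd.Series
    centers: pd.Series
    threshold: float

    def __post_init__(self) -> None:
        w = self.weights.to_numpy()
        if not np.isfinite(w).all():
            raise ValueError("non-finite discriminant weights")
        if not (w != 0).any():
            raise ValueError("all discriminant weights are zero")

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "weights": {g: float(w) for g, w in self.weights.items()},
            "centers": {g: float(c) for g, c in self.centers.items()},
            "threshold": float(self.threshold),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscriminantModel":
        return cls(
            genes=list(d["genes"]),
            weights=pd.Series(d["weights"], dtype=float),
            centers=pd.Series(d["centers"], dtype=float),
            threshold=float(d["threshold"]),
        )


# ---------------------------------------------------------------------------
# helpers


def label_agreement(a, b) -> float:
    """Agreement between two binary label vectors after optimal class
    matching: max(mean equal, mean unequal)."""
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("label vectors must be non-empty and equal-length")
    eq = float((a == b).mean())
    return max(eq, 1.0 - eq)


def _as_array(matrix) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(matrix, ExpressionMatrix):
        df = matrix.values
    else:
        df = matrix
    X = np.ascontiguousarray(df.to_numpy(dtype=float))
    return X, list(df.index), list(df.columns)


def _variance_floor(X: np.ndarray) -> float:
    v = X.var(axis=1, ddof=1)
    s0 = float(np.median(v))
    return s0 if s0 > 0 else 1e-8


def _tstats(X: np.ndarray, lab: np.ndarray, s0: float) -> np.ndarray:
    n1 = int(lab.sum())
    n0 = lab.size - n1
    m1 = X[:, lab == 1].mean(axis=1)
    m0 = X[:, lab == 0].mean(axis=1)
    v1 = X[:, lab == 1].var(axis=1, ddof=1) * (n1 - 1)
    v0 = X[:, lab == 0].var(axis=1, ddof=1) * (n0 - 1)
    sp2 = np.maximum((v1 + v0) / (n1 + n0 - 2), 0.0)
    return (m1 - m0) / np.sqrt((sp2 + s0) * (1.0 / n1 + 1.0 / n0))


def split_score(matrix, labels, m: int = 100, s0: float | None = None):
    """Score a given bipartition: mean of the ``m`` largest squared moderated
    t-statistics. Returns ``(score, module_gene_ids)``; symmetric under label
    swap."""
    X, genes, samples = _as_array(matrix)
    lab = np.asarray(labels, dtype=int)
    if lab.size != X.shape[1]:
        raise ValueError("labels length must match sample count")
    n1 = int((lab == 1).sum())
    if min(n1, lab.size - n1) < 2:
        raise ValueError("each class needs at least 2 samples")
    if s0 is None:
        s0 = _variance_floor(X)
    t = _tstats(X, lab, s0)
    m_eff = min(m, len(genes))
    order = np.argsort(-np.abs(t), kind="stable")[:m_eff]
    score = float((t[order] ** 2).mean())
    return score, [genes[i] for i in order]


def _canonical(lab: np.ndarray) -> np.ndarray:
    """g1 (label 1) is the smaller class; on a tie, the class not containing
    the first sample."""
    n1 = int(lab.sum())
    n0 = lab.size - n1
    if n1 > n0 or (n1 == n0 and lab[0] == 1):
        return 1 - lab
    return lab.copy()


def _split_1d(values: np.ndarray, min_size: int, by_gap: bool) -> np.ndarray | None:
    """Threshold split of a 1-D score vector with both sides >= min_size.
    ``by_gap``: cut at the largest gap between consecutive sorted values;
    otherwise at the optimal 2-means (minimum within-class SS) position."""
    n = values.size
    if n < 2 * min_size:
        return None
    order = np.argsort(values, kind="stable")
    v = values[order]
    lo, hi = min_size, n - min_size  # allowed cut positions (left size)
    if lo >= hi + 1:
        return None
    if by_gap:
        # cut before position i (left block size i) for i in [lo, hi)
        gaps = v[lo:hi] - v[lo - 1:hi - 1]
        cut = lo if gaps.size == 0 else lo + int(np.argmax(gaps))
    else:
        csum = np.cumsum(v)
        tot = csum[-1]
        sizes = np.arange(lo, hi)
        left = csum[lo - 1:hi - 1]
        # within-SS up to an additive constant: -(L^2/nL + R^2/nR)
        crit = -(left**2 / sizes + (tot - left) ** 2 / (n - sizes))
        cut = lo + int(np.argmin(crit))
    lab = np.zeros(n, dtype=np.uint8)
    lab[order[cut:]] = 1
    return _canonical(lab).astype(np.uint8)


def _candidate_seeds(X: np.ndarray, min_size: int, n_pcs: int = 10,
                     n_gap_genes: int = 200) -> list[np.ndarray]:
    G, n = X.shape
    seeds: list[np.ndarray] = []
    centered = X - X.mean(axis=1, keepdims=True)
    # 2-means on each leading principal component of the sample cloud
    try:
        u, s, vt = np.linalg.svd(centered.T, full_matrices=False)
        for i in range(min(n_pcs, s.size)):
            if s[i] <= 0:
                break
            lab = _split_1d(u[:, i] * s[i], min_size, by_gap=False)
            if lab is not None:
                seeds.append(lab)
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate input
        pass
    # largest-gap threshold splits on the most variable genes
    var = X.var(axis=1, ddof=1)
    top = np.argsort(-var, kind="stable")[: min(n_gap_genes, G)]
    for g in top:
        lab = _split_1d(X[g], min_size, by_gap=True)
        if lab is not None:
            seeds.append(lab)
    # dedupe identical seed labelings, preserving order
    seen = set()
    out = []
    for lab in seeds:
        key = lab.tobytes()
        if key not in seen:
            seen.add(key)
            out.append(lab)
    return out


def _search_core(X: np.ndarray, m: int, min_size: int, refine_top: int,
                 max_sweeps: int, s0: float) -> list[tuple[np.ndarray, float]]:
    """Seed, score, refine. Deterministic. Returns refined (labels, score)
    pairs sorted by decreasing score, deduplicated on exact labels."""
    seeds = _candidate_seeds(X, min_size)
    if not seeds:
        return []
    G, n = X.shape
    buf = np.empty(G)
    tot_sum = X.sum(axis=1)
    tot_ss = (X**2).sum(axis=1)
    m_eff = min(m, G)
    init_scores = []
    for lab in seeds:
        mask = lab == 1
        sc = _score_kernel(
            X[:, mask].sum(axis=1), (X[:, mask] ** 2).sum(axis=1),
            int(mask.sum()), tot_sum, tot_ss, n, s0, m_eff, buf,
        )
        init_scores.append(sc)
    order = np.argsort(-np.asarray(init_scores), kind="stable")[:refine_top]
    results: dict[bytes, tuple[np.ndarray, float]] = {}
    for i in order:
        lab = seeds[i].copy()
        sc = _refine_kernel(X, lab, m_eff, s0, min_size, max_sweeps)
        lab = _canonical(lab.astype(int)).astype(np.uint8)
        key = lab.tobytes()
        if key not in results or sc > results[key][1]:
            results[key] = (lab, float(sc))
    out = sorted(results.values(), key=lambda p: -p[1])
    return out


def search_splits(matrix, m: int = 100, max_splits: int = 6,
                  min_group_size: int | None = None, redundancy_max: float = 0.8,
                  n_perm: int = 99, alpha: float = 0.05, seed: int = 0,
                  refine_top: int = 25, max_sweeps: int = 50) -> list[Bipartition]:
    """Discover significant binary partitions of the samples.

    Candidates are seeded from 2-means splits on the top 10 principal
    components and largest-gap splits on the 200 most variable genes; the
    ``refine_top`` best-scoring seeds are hill-climbed. With ``n_perm > 0``,
    candidates are tested against a permutation null (max refined score over
    gene-wise column shuffles, same search) and kept when ``p < alpha``.
    Near-duplicate partitions (agreement > ``redundancy_max``) are collapsed
    to the higher-scoring one. May return an empty list: no supported
    partition is a valid outcome. Deterministic given ``seed``.
    """
    X, genes, samples = _as_array(matrix)
    n = X.shape[1]
    if min_group_size is None:
        min_group_size = max(5, round(0.1 * n))
    if min_group_size > n // 2:
        raise ValueError(
            f"min_group_size={min_group_size} infeasible for {n} samples"
        )
    if n_perm > 0 and 1.0 / (n_perm + 1.0) >= alpha:
        raise ValueError(
            f"n_perm={n_perm} cannot reach significance below alpha={alpha}; "
            f"need n_perm > {int(np.ceil(1.0 / alpha)) - 1}"
        )
    s0 = _variance_floor(X)
    refined = _search_core(X, m, min_group_size, refine_top, max_sweeps, s0)
    if not refined:
        return []

    pvals: list[float | None]
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        null_max = np.empty(n_perm)
        for p in range(n_perm):
            Xp = rng.permuted(X, axis=1)  # each gene shuffled independently
            s0_p = _variance_floor(Xp)
            res = _search_core(Xp, m, min_group_size, refine_top, max_sweeps, s0_p)
            null_max[p] = res[0][1] if res else 0.0
        kept = []
        for lab, sc in refined:
            pv = (1.0 + float((null_max >= sc).sum())) / (n_perm + 1.0)
            if pv < alpha:
                kept.append((lab, sc, pv))
    else:
        kept = [(lab, sc, None) for lab, sc in refined]

    # redundancy pruning, highest score first
    selected: list[tuple[np.ndarray, float, float | None]] = []
    for lab, sc, pv in kept:
        if all(label_agreement(lab, prev[0]) <= redundancy_max for prev in selected):
            selected.append((lab, sc, pv))
        if len(selected) >= max_splits:
            break

    out = []
    for lab, sc, pv in selected:
        score, module = split_score(matrix, lab, m=m, s0=s0)
        t = _tstats(X, lab.astype(int), s0)
        gene_pos = {g: i for i, g in enumerate(genes)}
        t_mod = pd.Series({g: float(t[gene_pos[g]]) for g in module})
        bp = Bipartition(
            labels=pd.Series(lab.astype(int), index=samples),
            module=module,
            t_stats=t_mod,
            score=score,
            pvalue=pv,
        )
        model = lda_train(matrix, bp)
        bp.weights = model.weights
        out.append(bp)
    return out


# ---------------------------------------------------------------------------
# diagonal LDA


def lda_train(matrix, bipartition: Bipartition, s0: float | None = None) -> DiscriminantModel:
    """Fit a diagonal linear discriminant on the partition's module genes."""
    X_df = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    lab = bipartition.labels.reindex(X_df.columns)
    if lab.isna().any():
        raise ValueError("bipartition labels missing for some matrix samples")
    lab = lab.to_numpy(dtype=int)
    module = [g for g in bipartition.module if g in X_df.index]
    if not module:
        raise ValueError("no module genes present in matrix")
    M = X_df.loc[module].to_numpy(dtype=float)
    n1 = int(lab.sum())
    n0 = lab.size - n1
    m1 = M[:, lab == 1].mean(axis=1)
    m0 = M[:, lab == 0].mean(axis=1)
    v1 = M[:, lab == 1].var(axis=1, ddof=1) * (n1 - 1)
    v0 = M[:, lab == 0].var(axis=1, ddof=1) * (n0 - 1)
    sp2 = np.maximum((v1 + v0) / (n1 + n0 - 2), 0.0)
    if s0 is None:
        floor = float(np.median(sp2))
        s0 = floor if floor > 0 else 1e-8
    w = (m1 - m0) / (sp2 + s0)
    centers = (m1 + m0) / 2.0
    proj = w @ (M - centers[:, None])
    threshold = _equal_error_threshold(proj, lab)
    return DiscriminantModel(
        genes=list(module),
        weights=pd.Series(w, index=module),
        centers=pd.Series(centers, index=module),
        threshold=threshold,
    )


def _equal_error_threshold(proj: np.ndarray, lab: np.ndarray) -> float:
    """Threshold at the training equal-error point: minimizes |FNR - FPR|,
    ties broken by total error then by lower threshold."""
    order = np.argsort(proj, kind="stable")
    p = proj[order]
    y = lab[order]
    n1 = int(y.sum())
    n0 = y.size - n1
    # candidate cuts between consecutive points plus the two extremes
    cands = np.concatenate(([p[0] - 1.0], (p[:-1] + p[1:]) / 2.0, [p[-1] + 1.0]))
    best = None
    for thr in cands:
        pred = p > thr
        fn = int((~pred & (y == 1)).sum()) / max(n1, 1)
        fp = int((pred & (y == 0)).sum()) / max(n0, 1)
        key = (abs(fn - fp), fn + fp, thr)
        if best is None or key < best[0]:
            best = (key, thr)
    return float(best[1])


def lda_predict(model: DiscriminantModel, matrix):
    """Predict g0/g1 labels and continuous projections for new samples.

    Module genes missing from the matrix are dropped and the projection is
    renormalized by the retained share of total absolute weight (with a
    warning); all genes missing is an error.
    """
    X_df = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    present = [g for g in model.genes if g in X_df.index]
    if not present:
        raise ValueError("no module genes present in prediction matrix")
    if len(present) < len(model.genes):
        warnings.warn(
            f"{len(model.genes) - len(present)} of {len(model.genes)} module genes "
            "missing; projection renormalized",
            stacklevel=2,
        )
    w = model.weights[present].to_numpy()
    c = model.centers[present].to_numpy()
    full = float(model.weights.abs().sum())
    avail = float(np.abs(w).sum())
    scale = full / avail if avail > 0 else 1.0
    M = X_df.loc[present].to_numpy(dtype=float)
    proj = scale * (w @ (M - c[:, None]))
    labels = (proj > model.threshold).astype(int)
    return (
        pd.Series(labels, index=X_df.columns),
        pd.Series(proj, index=X_df.columns),
    )
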