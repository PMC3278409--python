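"""Portable subtype scoring of expression cohorts with a weighted gene
signature.

A cohort on any platform is mapped to the signature's gene namespace, each
gene robustly rescaled to [-1, 1] by quantile clipping, and every sample
assigned the normalized weighted score

    score_s = sum_g w_g x_gs / sum_g |w_g|   in [-1, 1],

where the weights come from the discriminant trained on the discovery
cohort (positive = higher in the angiogenic class). Bimodality of the score
distribution is assessed with univariate Gaussian mixtures selected by BIC;
with k >= 2 components, samples whose posterior mass favors the highest-mean
component are called angiogenic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = [
    "map_genes",
    "robust_scale",
    "signature_score",
    "MixtureFit",
    "gmm_bic",
    "classify_subtype",
    "SubtypeScoreSet",
]

log = logging.getLogger(__name__)


def map_genes(matrix, id_map: dict[str, str]):
    """Collapse a probe-level matrix onto genes via a many-to-one map.

    When several probes map to one gene, the probe with maximal variance
    across samples is retained; unmapped probes are dropped (count logged).
    """
    df = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    mapped = {p: id_map[p] for p in df.index if p in id_map}
    n_dropped = len(df.index) - len(mapped)
    if n_dropped:
        log.info("map_genes: dropped %d unmapped probes", n_dropped)
    if not mapped:
        raise ValueError("no probes could be mapped to the target namespace")
    var = df.var(axis=1, ddof=1)
    best: dict[str, str] = {}
    for probe, gene in mapped.items():
        if gene not in best or (var[probe], probe) > (var[best[gene]], best[gene]):
            # tie on variance breaks by probe ID for determinism
            best[gene] = probe
    genes = sorted(best)
    out = df.loc[[best[g] for g in genes]].copy()
    out.index = genes
    return ExpressionMatrix(out) if isinstance(matrix, ExpressionMatrix) else out


def robust_scale(matrix, q: float = 0.025):
    """Per-gene robust rescaling to [-1, 1].

    Values are clipped at the ``q`` and ``1-q`` quantiles and those quantiles
    mapped affinely to -1 and +1; genes constant after clipping map to 0.
    Invariant to positive-slope per-gene affine transforms of the input.
    """
    if q >= 0.5:
        raise ValueError("q must be below 0.5")
    df = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if df.shape[1] < 3:
        raise ValueError("robust scaling needs at least 3 samples")
    X = df.to_numpy(dtype=float)
    lo = np.quantile(X, q, axis=1)
    hi = np.quantile(X, 1.0 - q, axis=1)
    span = hi - lo
    const = span <= 0
    span_safe = np.where(const, 1.0, span)
    clipped = np.clip(X, lo[:, None], hi[:, None])
    scaled = 2.0 * (clipped - lo[:, None]) / span_safe[:, None] - 1.0
    scaled[const] = 0.0
    out = pd.DataFrame(scaled, index=df.index, columns=df.columns)
    return ExpressionMatrix(out) if isinstance(matrix, ExpressionMatrix) else out


def signature_score(scaled_matrix, weights: pd.Series) -> pd.Series:
    """Weighted signature score per sample over available signature genes:
    ``sum w_g x_gs / sum |w_g|``; lies in [-1, 1] for inputs in [-1, 1]."""
    df = scaled_matrix.values if isinstance(scaled_matrix, ExpressionMatrix) else scaled_matrix
    present = [g for g in weights.index if g in df.index]
    if not present:
        raise ValueError("no signature genes present in the matrix")
    if len(present) < len(weights):
        log.info(
            "signature_score: %d of %d signature genes available",
            len(present), len(weights),
        )
    w = weights[present].to_numpy(dtype=float)
    denom = np.abs(w).sum()
    if denom == 0:
        raise ValueError("signature weights sum to zero absolute mass")
    X = df.loc[present].to_numpy(dtype=float)
    return pd.Series(w @ X / denom, index=df.columns, name="score")


# ---------------------------------------------------------------------------
# univariate Gaussian mixtures by EM, model size by BIC


@dataclass(eq=False)
class MixtureFit:
    k: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik: float
    bic: float
    loglik_trace: list[float] = field(default_factory=list)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        comp = self.weights[:, None] * _normal_pdf(
            x[None, :], self.means[:, None], self.variances[:, None]
        )
        return comp.sum(axis=0)

    def posteriors(self, x: np.ndarray) -> np.ndarray:
        """(k, n) posterior component responsibilities."""
        x = np.asarray(x, dtype=float)
        comp = self.weights[:, None] * _normal_pdf(
            x[None, :], self.means[:, None], self.variances[:, None]
        )
        tot = comp.sum(axis=0)
        tot = np.where(tot <= 0, np.finfo(float).tiny, tot)
        return comp / tot


def _normal_pdf(x, mean, var):
    return np.exp(-0.5 * (x - mean) ** 2 / var) / np.sqrt(2.0 * np.pi * var)


def _kmeans_1d(x: np.ndarray, k: int, rng, n_iter: int = 50) -> np.ndarray:
    centers = np.sort(rng.choice(x, size=k, replace=False))
    for _ in range(n_iter):
        assign = np.argmin(np.abs(x[None, :] - centers[:, None]), axis=0)
        new = np.array(
            [x[assign == j].mean() if (assign == j).any() else centers[j] for j in range(k)]
        )
        if np.allclose(new, centers):
            break
        centers = new
    return centers


def _em_fit(x: np.ndarray, k: int, rng, tol: float, max_iter: int) -> MixtureFit:
    n = x.size
    var_floor = max(1e-6 * float(x.var()), 1e-12)
    if k == 1:
        mu = float(x.mean())
        var = max(float(x.var()), var_floor)
        ll = float(np.log(_normal_pdf(x, mu, var)).sum())
        return MixtureFit(1, np.array([1.0]), np.array([mu]), np.array([var]),
                          ll, -2.0 * ll + 2.0 * np.log(n), [ll])
    centers = _kmeans_1d(x, k, rng)
    assign = np.argmin(np.abs(x[None, :] - centers[:, None]), axis=0)
    w = np.array([(assign == j).mean() for j in range(k)])
    w = np.where(w <= 0, 1.0 / n, w)
    w /= w.sum()
    mu = centers.astype(float)
    var = np.array(
        [max(x[assign == j].var(), var_floor) if (assign == j).sum() > 1 else float(x.var())
         for j in range(k)]
    )
    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        comp = w[:, None] * _normal_pdf(x[None, :], mu[:, None], var[:, None])
        tot = comp.sum(axis=0)
        tot = np.where(tot <= 0, np.finfo(float).tiny, tot)
        ll = float(np.log(tot).sum())
        trace.append(ll)
        r = comp / tot  # responsibilities (k, n)
        nk = r.sum(axis=1)
        nk = np.where(nk <= 0, np.finfo(float).tiny, nk)
        w = nk / n
        mu = (r @ x) / nk
        var = np.maximum((r @ (x**2)) / nk - mu**2, var_floor)
        if ll - prev < tol and np.isfinite(prev):
            break
        prev = ll
    ll = trace[-1]
    p = 3 * k - 1
    return MixtureFit(k, w, mu, var, ll, -2.0 * ll + p * np.log(n), trace)


def gmm_bic(scores, k_max: int = 5, n_restarts: int = 3, seed: int = 0,
            tol: float = 1e-6, max_iter: int = 500):
    """Fit univariate Gaussian mixtures for k = 1..k_max and pick k by BIC.

    EM with k-means initialization and ``n_restarts`` seeded restarts per k;
    BIC = -2 loglik + (3k - 1) ln n. Returns ``(best_k, fits)`` where
    ``fits[k]`` is the best :class:`MixtureFit` for each k.
    """
    x = np.asarray(scores, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 20:
        raise ValueError("need at least 20 scores")
    if x.size < 4 * k_max:
        raise ValueError(f"need at least 4*k_max = {4 * k_max} scores, got {x.size}")
    rng = np.random.default_rng(seed)
    fits: dict[int, MixtureFit] = {}
    for k in range(1, k_max + 1):
        best = None
        for _ in range(max(1, n_restarts)):
            fit = _em_fit(x, k, rng, tol, max_iter)
            if best is None or fit.loglik > best.loglik:
                best = fit
        fits[k] = best
    best_k = min(fits, key=lambda k: (fits[k].bic, k))
    return best_k, fits


@dataclass(eq=False)
class SubtypeScoreSet:
    scores: pd.Series
    mixture: MixtureFit
    best_k: int
    calls: pd.Series | None  # "angiogenic" / "non-angiogenic"; None when k = 1
    boundary: float | None

    def to_frame(self) -> pd.DataFrame:
        df = self.scores.to_frame("score")
        df["call"] = self.calls if self.calls is not None else "no-subtype"
        return df


def classify_subtype(scores: pd.Series, mixture: MixtureFit):
    """Call angiogenic vs non-angiogenic from the mixture over scores.

    The highest-mean component is the angiogenic ("upper") one; a sample is
    called angiogenic when its posterior mass on that component exceeds 0.5.
    With a single component a no-subtype flag (``calls=None``) is returned.
    Also reports the decision-boundary score (posterior crossing 0.5).
    """
    x = np.asarray(scores, dtype=float)
    if mixture.k < 2:
        return SubtypeScoreSet(pd.Series(scores), mixture, mixture.k, None, None)
    upper = int(np.argmax(mixture.means))
    post = mixture.posteriors(x)[upper]
    calls = pd.Series(
        np.where(post > 0.5, "angiogenic", "non-angiogenic"), index=scores.index
    )
    # boundary: smallest grid score above which the upper component wins
    grid = np.linspace(float(min(x.min(), mixture.means.min())),
                       float(max(x.max(), mixture.means.max())), 2001)
    pg = mixture.posteriors(grid)[upper]
    above = pg > 0.5
    boundary = None
    if above.any() and not above.all():
        i = int(np.argmax(above))
        boundary = float((grid[i - 1] + grid[i]) / 2.0) if i > 0 else float(grid[0])
    return SubtypeScoreSet(pd.Series(scores), mixture, mixture.k, calls, boundary)
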