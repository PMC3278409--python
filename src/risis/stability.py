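"""Bootstrap stability gating of discovered partitions.

For each bootstrap replicate, the partition search is re-run on a random
subset of the training samples; a replicate split matching a base split
(label agreement >= 0.75 on the shared samples) trains a discriminant whose
predictions on the replicate's held-out samples are compared with the base
labels. The stability of a base split is the mean of those held-out
agreements across matched replicates; splits with stability > 0.95 are
retained, then re-confirmed on the untouched model-selection set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix
from .isis import (
    Bipartition,
    lda_predict,
    lda_train,
    search_splits,
)

__all__ = ["StableSplit", "bootstrap_stability", "retain_stable", "confirm_on_holdout"]


@dataclass(eq=False)
class StableSplit:
    base: Bipartition
    stability: float
    n_boot: int
    matched_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.stability <= 1.0:
            raise ValueError("stability must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "base": self.base.to_dict(),
            "stability": float(self.stability),
            "n_boot": int(self.n_boot),
            "matched_fraction": float(self.matched_fraction),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StableSplit":
        return cls(
            base=Bipartition.from_dict(d["base"]),
            stability=float(d["stability"]),
            n_boot=int(d["n_boot"]),
            matched_fraction=float(d["matched_fraction"]),
        )


def _oriented_agreement(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    """Agreement and whether the optimal class matching flips ``b``."""
    eq = float((a == b).mean())
    if eq >= 1.0 - eq:
        return eq, False
    return 1.0 - eq, True


def bootstrap_stability(matrix: ExpressionMatrix, base_splits, n_boot: int = 100,
                        train_fraction: float = 0.63, seed: int = 0,
                        match_threshold: float = 0.75, m: int = 100,
                        min_group_size: int | None = None,
                        refine_top: int = 25) -> list[StableSplit]:
    """Estimate classification stability of each base split under resampling.

    Per replicate: ``floor(train_fraction * n)`` samples are drawn without
    replacement, the search is re-run on them (no permutation filter — the
    match-to-base criterion plays that role here), each discovered split is
    matched to each base split by label agreement on the subset, and the
    matched split's discriminant predicts the held-out samples. Stability is
    the mean held-out agreement with the base labels over matched replicates
    (0.0 if no replicate matched); ``matched_fraction`` reports how often a
    match was found.
    """
    if n_boot < 10:
        raise ValueError("n_boot must be at least 10 for a usable estimate")
    if not 0.0 < train_fraction <= 1.0:
        raise ValueError("train_fraction must be in (0, 1]")
    base_splits = list(base_splits)
    samples = matrix.samples
    n = len(samples)
    n_sub = math.floor(train_fraction * n)
    if n_sub < 4 or (train_fraction < 1.0 and n_sub >= n):
        raise ValueError(f"subset size {n_sub} of {n} is unusable")
    rng = np.random.default_rng(seed)
    base_labels = [
        bp.labels.reindex(samples).to_numpy(dtype=int) for bp in base_splits
    ]
    if any(np.isnan(b).any() for b in
           (bp.labels.reindex(samples).to_numpy(dtype=float) for bp in base_splits)):
        raise ValueError("base split labels missing for some matrix samples")

    agree_sums = [0.0] * len(base_splits)
    match_counts = [0] * len(base_splits)
    for _b in range(n_boot):
        idx = np.sort(rng.choice(n, size=n_sub, replace=False))
        sub_ids = [samples[i] for i in idx]
        held = np.setdiff1d(np.arange(n), idx)
        sub = matrix.subset_samples(sub_ids)
        rep_splits = search_splits(
            sub, m=m, max_splits=len(base_splits) + 2,
            min_group_size=min_group_size, n_perm=0,
            refine_top=refine_top,
        )
        if not rep_splits:
            continue
        rep_labels = [bp.labels.to_numpy(dtype=int) for bp in rep_splits]
        for k, base in enumerate(base_labels):
            base_sub = base[idx]
            best = None
            for bp, lab in zip(rep_splits, rep_labels):
                ag, flip = _oriented_agreement(base_sub, lab)
                if best is None or ag > best[0]:
                    best = (ag, flip, bp)
            ag, flip, bp = best
            if ag < match_threshold:
                continue
            match_counts[k] += 1
            if held.size == 0 or train_fraction >= 1.0:
                # no held-out samples: the rediscovered split itself is the
                # evidence; score its agreement with the base on the subset
                agree_sums[k] += ag
                continue
            model = lda_train(sub, bp)
            held_ids = [samples[i] for i in held]
            pred, _ = lda_predict(model, matrix.subset_samples(held_ids))
            pred = pred.to_numpy(dtype=int)
            if flip:
                pred = 1 - pred
            agree_sums[k] += float((pred == base[held]).mean())

    out = []
    for k, bp in enumerate(base_splits):
        mc = match_counts[k]
        stability = agree_sums[k] / mc if mc else 0.0
        out.append(
            StableSplit(
                base=bp,
                stability=min(1.0, stability),
                n_boot=n_boot,
                matched_fraction=mc / n_boot,
            )
        )
    return out


def retain_stable(splits, threshold: float = 0.95) -> list[StableSplit]:
    """Keep splits whose stability strictly exceeds ``threshold``; order
    preserved."""
    return [s for s in splits if s.stability > threshold]


def confirm_on_holdout(retained, train_matrix: ExpressionMatrix,
                       model_matrix: ExpressionMatrix, n_boot: int = 100,
                       train_fraction: float = 0.63, threshold: float = 0.95,
                       seed: int = 0, m: int = 100, match_threshold: float = 0.75,
                       min_group_size: int | None = None,
                       refine_top: int = 25) -> list[StableSplit]:
    """Confirm retained splits on the disjoint model-selection samples.

    The discriminant trained on the full training labels fixes reference
    labels on the model-selection samples. Each bootstrap replicate then
    re-searches a random training subset; when a discovered split matches the
    base split (agreement >= ``match_threshold`` on the subset), its
    classifier predicts the model-selection samples and the agreement with
    the reference labels is recorded. A split is confirmed when that mean
    prediction consistency exceeds ``threshold``. A noise split is never
    matched by replicate searches and therefore scores 0.
    """
    overlap = set(train_matrix.samples) & set(model_matrix.samples)
    if overlap:
        raise ValueError(
            f"training and model-selection samples overlap: {sorted(overlap)[:3]}"
        )
    if n_boot < 10:
        raise ValueError("n_boot must be at least 10 for a usable estimate")
    rng = np.random.default_rng(seed)
    samples = train_matrix.samples
    n = len(samples)
    n_sub = math.floor(train_fraction * n)

    refs = []
    for st in retained:
        model = lda_train(train_matrix, st.base)
        pred, _ = lda_predict(model, model_matrix)
        lab = pred.to_numpy(dtype=int)
        degenerate = min(lab.sum(), lab.size - lab.sum()) < 2
        refs.append(None if degenerate else lab)

    base_labels = [
        st.base.labels.reindex(samples).to_numpy(dtype=int) for st in retained
    ]
    agree_sums = [0.0] * len(retained)
    match_counts = [0] * len(retained)
    for _b in range(n_boot):
        idx = np.sort(rng.choice(n, size=n_sub, replace=False))
        sub = train_matrix.subset_samples([samples[i] for i in idx])
        rep_splits = search_splits(
            sub, m=m, max_splits=len(retained) + 2,
            min_group_size=min_group_size, n_perm=0, refine_top=refine_top,
        )
        if not rep_splits:
            continue
        rep_labels = [bp.labels.to_numpy(dtype=int) for bp in rep_splits]
        for k, base in enumerate(base_labels):
            if refs[k] is None:
                continue
            best = None
            for bp, lab in zip(rep_splits, rep_labels):
                ag, flip = _oriented_agreement(base[idx], lab)
                if best is None or ag > best[0]:
                    best = (ag, flip, bp)
            ag, flip, bp = best
            if ag < match_threshold:
                continue
            match_counts[k] += 1
            rep_model = lda_train(sub, bp)
            pred, _ = lda_predict(rep_model, model_matrix)
            pred = pred.to_numpy(dtype=int)
            if flip:
                pred = 1 - pred
            agree_sums[k] += float((pred == refs[k]).mean())

    confirmed = []
    for k, st in enumerate(retained):
        mc = match_counts[k]
        stability = agree_sums[k] / mc if mc else 0.0
        if stability > threshold:
            confirmed.append(
                StableSplit(
                    base=st.base,
                    stability=min(1.0, stability),
                    n_boot=n_boot,
                    matched_fraction=mc / n_boot,
                )
            )
    return confirmed
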