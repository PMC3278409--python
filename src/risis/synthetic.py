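"""Synthetic tumor-expression cohorts with planted binary subtypes.

Emulates the statistical structure of a bulk expression study of a single
tumor histology: a genes × samples matrix on a log2-like intensity scale, a
handful of technical duplicate samples, up to four planted binary partitions
each supported by a disjoint ~100-gene module, a microRNA matrix whose
informative features track the first partition, exponential survival with a
subtype-dependent hazard, and categorical clinical covariates.

The expression model is additive::

    X[g, s] = mu_g + sum_k delta_k * 1[g in module_k] * 1[s in g1_k] + eps,
    eps ~ Normal(0, noise_sd^2),  mu_g ~ Normal(8, 1.5^2)

Duplicate samples are re-noised copies of their source sample's noiseless
profile, appended as extra columns with a ``-dup`` suffix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import ExpressionMatrix

__all__ = [
    "PlantedSplit",
    "CohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "generate_survival",
    "generate_mirna",
    "generate_clinical",
]

BASELINE_MEAN = 8.0
BASELINE_SD = 1.5


@dataclass(frozen=True)
class PlantedSplit:
    """A planted binary partition: a minority class of size ``fraction_g1``
    whose samples are shifted by ``effect`` on a disjoint ``module_size``-gene
    module."""

    fraction_g1: float
    module_size: int = 100
    effect: float = 2.5

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction_g1 < 0.5:
            raise ValueError(f"fraction_g1 must be in (0, 0.5), got {self.fraction_g1}")
        if self.module_size <= 0:
            raise ValueError("module_size must be positive")


def default_planted_splits() -> list[PlantedSplit]:
    # Minority fractions for the first two mirror observed class sizes
    # (33/129 and 46/129); the last two fill in distinct intermediate sizes.
    return [
        PlantedSplit(fraction_g1=33 / 129),
        PlantedSplit(fraction_g1=46 / 129),
        PlantedSplit(fraction_g1=0.30),
        PlantedSplit(fraction_g1=0.42),
    ]


@dataclass
class CohortSpec:
    n_samples: int = 129
    n_genes: int = 12000
    n_duplicates: int = 12
    planted_splits: list[PlantedSplit] = field(default_factory=default_planted_splits)
    noise_sd: float = 1.0
    n_mirna: int = 743
    mirna_informative: int = 40
    mirna_effect: float = 2.0
    hr: float = 1.3
    baseline_rate: float = 0.1
    censor_frac: float = 0.3
    clinical_log_odds: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "n_mirna"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_duplicates < 0 or self.n_duplicates > self.n_samples:
            raise ValueError("need 0 <= n_duplicates <= n_samples")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.mirna_informative > self.n_mirna:
            raise ValueError(
                f"mirna_informative ({self.mirna_informative}) exceeds n_mirna ({self.n_mirna})"
            )
        total_module = sum(s.module_size for s in self.planted_splits)
        if total_module > self.n_genes:
            raise ValueError(
                f"disjoint modules need {total_module} genes but n_genes={self.n_genes}"
            )


@dataclass
class SyntheticCohort:
    """A generated cohort bundle.

    ``expression`` has ``n_samples + n_duplicates`` columns (duplicates carry
    a ``-dup`` suffix); truth labels, survival and clinical tables cover the
    unique samples only.
    """

    expression: ExpressionMatrix
    mirna: ExpressionMatrix
    truth_labels: pd.DataFrame  # samples × splits, values 0/1 (1 = minority g1)
    modules: dict[str, list[str]]
    duplicate_pairs: list[tuple[str, str]]
    survival: pd.DataFrame  # columns: time, event
    clinical: pd.DataFrame  # columns: grade, stage, debulking
    spec: CohortSpec

    @property
    def unique_samples(self) -> list[str]:
        return list(self.truth_labels.index)


def _sample_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"s{i + 1:0{width}d}" for i in range(n)]


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full synthetic cohort, deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_samples, spec.n_genes
    genes = [f"g{i + 1:05d}" for i in range(g)]
    samples = _sample_ids(n)

    mu = rng.normal(BASELINE_MEAN, BASELINE_SD, size=g)
    clean = np.tile(mu[:, None], (1, n))

    # Disjoint module gene indices drawn without replacement across all splits.
    total_module = sum(s.module_size for s in spec.planted_splits)
    module_pool = rng.choice(g, size=total_module, replace=False)
    labels = {}
    modules = {}
    offset = 0
    for k, split in enumerate(spec.planted_splits, start=1):
        name = f"S{k}"
        idx = module_pool[offset : offset + split.module_size]
        offset += split.module_size
        n_g1 = max(1, round(split.fraction_g1 * n))
        g1 = rng.choice(n, size=n_g1, replace=False)
        lab = np.zeros(n, dtype=int)
        lab[g1] = 1
        clean[np.ix_(idx, g1)] += split.effect * spec.noise_sd
        labels[name] = lab
        modules[name] = [genes[i] for i in idx]

    X = clean + rng.normal(0.0, spec.noise_sd, size=(g, n))

    # Technical duplicates: fresh noise on the same clean profile.
    dup_src = rng.choice(n, size=spec.n_duplicates, replace=False)
    pairs = []
    dup_cols = []
    dup_ids = []
    for i in dup_src:
        sid = samples[i]
        dup_ids.append(f"{sid}-dup")
        pairs.append((sid, f"{sid}-dup"))
        dup_cols.append(clean[:, i] + rng.normal(0.0, spec.noise_sd, size=g))
    if dup_cols:
        X = np.concatenate([X, np.stack(dup_cols, axis=1)], axis=1)

    expr = ExpressionMatrix(
        pd.DataFrame(X, index=genes, columns=samples + dup_ids), pairs
    )
    truth = pd.DataFrame(labels, index=pd.Index(samples, name="sample_id"))

    split1 = truth.iloc[:, 0].to_numpy() if len(spec.planted_splits) else np.zeros(n, int)
    mirna = generate_mirna(pd.Series(split1, index=samples), spec,
                           seed=int(rng.integers(2**31)))
    survival = _survival_table(
        pd.Series(split1, index=samples),
        hr=spec.hr,
        baseline_rate=spec.baseline_rate,
        censor_frac=spec.censor_frac,
        seed=int(rng.integers(2**31)),
    )
    clinical = generate_clinical(
        pd.Series(split1, index=samples),
        log_odds=spec.clinical_log_odds,
        seed=int(rng.integers(2**31)),
    )
    return SyntheticCohort(expr, mirna, truth, modules, pairs, survival, clinical, spec)


def generate_survival(labels: pd.Series, hr: float, baseline_rate: float,
                      censor_frac: float = 0.3, seed: int = 0) -> pd.DataFrame:
    """Exponential survival with hazard ``baseline_rate`` for g0 and
    ``hr * baseline_rate`` for g1, censored by an independent Uniform(0, T)
    with T solved so the expected censoring fraction is ``censor_frac``.
    """
    if hr <= 0:
        raise ValueError("hr must be positive")
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    if not 0 <= censor_frac < 1:
        raise ValueError("censor_frac must be in [0, 1)")
    lab = np.asarray(labels, dtype=int)
    if lab.size == 0 or (lab == 1).sum() == 0 or (lab == 0).sum() == 0:
        raise ValueError("both groups g0 and g1 must be non-empty")
    return _survival_table(labels, hr, baseline_rate, censor_frac, seed)


def _survival_table(labels: pd.Series, hr: float, baseline_rate: float,
                    censor_frac: float, seed: int) -> pd.DataFrame:
    lab = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    rates = np.where(lab == 1, hr * baseline_rate, baseline_rate)
    times = rng.exponential(1.0 / rates)

    if censor_frac > 0:
        frac1 = float((lab == 1).mean())

        def expected_censoring(T: float) -> float:
            # P(U < E) for U~Unif(0,T), E~Exp(rate): (1 - exp(-rate*T))/(rate*T)
            out = 0.0
            for w, r in ((1 - frac1, baseline_rate), (frac1, hr * baseline_rate)):
                out += w * (1.0 - math.exp(-r * T)) / (r * T)
            return out

        # expected_censoring decreases from 1 (T->0) to 0 (T->inf)
        hi = 1.0 / baseline_rate
        while expected_censoring(hi) > censor_frac:
            hi *= 2.0
        T = brentq(lambda t: expected_censoring(t) - censor_frac, 1e-9, hi)
        cens = rng.uniform(0.0, T, size=lab.size)
        event = (times <= cens).astype(int)
        obs = np.minimum(times, cens)
    else:
        event = np.ones(lab.size, dtype=int)
        obs = times
    return pd.DataFrame(
        {"time": obs, "event": event, "group": lab}, index=labels.index
    )


def generate_mirna(labels_split1: pd.Series, spec: CohortSpec, seed: int = 0) -> ExpressionMatrix:
    """MicroRNA matrix: ``mirna_informative`` features shifted by
    ``mirna_effect * noise_sd`` between split-1 classes, the rest pure noise.
    Feature IDs are stable: ``mir0001`` ... ``mir{n_mirna}``.
    """
    if labels_split1.isna().any():
        raise ValueError("labels must be defined for all samples")
    if spec.mirna_informative > spec.n_mirna:
        raise ValueError("mirna_informative exceeds n_mirna")
    rng = np.random.default_rng(seed)
    lab = np.asarray(labels_split1, dtype=int)
    n = lab.size
    mu = rng.normal(BASELINE_MEAN, BASELINE_SD, size=spec.n_mirna)
    X = mu[:, None] + rng.normal(0.0, spec.noise_sd, size=(spec.n_mirna, n))
    X[: spec.mirna_informative, lab == 1] += spec.mirna_effect * spec.noise_sd
    ids = [f"mir{i + 1:04d}" for i in range(spec.n_mirna)]
    return ExpressionMatrix(pd.DataFrame(X, index=ids, columns=list(labels_split1.index)))


GRADE_FREQS = {"1": 0.05, "2": 0.20, "3": 0.65, "4": 0.10}
STAGE_FREQS = {"I": 0.05, "II": 0.05, "III": 0.70, "IV": 0.20}
DEBULKING_FREQS = {"optimal": 0.55, "suboptimal": 0.45}


def _sample_categorical(rng, freqs: dict[str, float], lab, log_odds: float):
    cats = list(freqs)
    base = np.array([freqs[c] for c in cats], dtype=float)
    base /= base.sum()
    out = []
    for is_g1 in lab:
        p = base.copy()
        if log_odds != 0.0 and is_g1:
            # tilt probability mass toward the last category for g1 samples
            logit = np.log(p) + log_odds * np.linspace(0, 1, len(p))
            p = np.exp(logit - logit.max())
            p /= p.sum()
        out.append(rng.choice(cats, p=p))
    return out


def generate_clinical(labels: pd.Series, log_odds: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Categorical clinical covariates (grade, stage, debulking) from fixed
    category frequencies, optionally tilted with the subtype label via
    ``log_odds`` (0 = independent of subtype)."""
    rng = np.random.default_rng(seed)
    lab = np.asarray(labels, dtype=int)
    return pd.DataFrame(
        {
            "grade": _sample_categorical(rng, GRADE_FREQS, lab, log_odds),
            "stage": _sample_categorical(rng, STAGE_FREQS, lab, log_odds),
            "debulking": _sample_categorical(rng, DEBULKING_FREQS, lab, log_odds),
        },
        index=labels.index,
    )
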