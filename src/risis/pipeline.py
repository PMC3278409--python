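"""End-to-end pipeline: simulate -> preprocess -> discover -> stability ->
miRNA validation -> subtype scoring -> clinical association -> enrichment.

A single integer seed in the config drives every stochastic stage through
fixed per-stage offsets, so a rerun with the same config reproduces every
artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .enrichment import hypergeom_enrich
from .io import (
    ExpressionMatrix,
    read_gmt,
    write_duplicate_pairs,
    write_expression,
    write_json,
    write_phenotype,
)
from .isis import lda_predict, lda_train, search_splits
from .pam import nested_cv
from .preprocess import filter_variable_genes, quantile_normalize, split_train_model_selection, vst_surrogate
from .scoring import classify_subtype, gmm_bic, robust_scale, signature_score
from .stability import bootstrap_stability, confirm_on_holdout, retain_stable
from .survival import cox_hr, fisher_exact, km_logrank, subtype_proportions
from .synthetic import CohortSpec, PlantedSplit, generate_cohort

log = logging.getLogger(__name__)

# fixed per-stage seed offsets derived from the single config seed
_STAGE_OFFSETS = {
    "simulate": 0,
    "split": 101,
    "discover": 202,
    "stability": 303,
    "confirm": 404,
    "mirna": 505,
    "gmm": 606,
    "fisher": 707,
}


@dataclass
class PipelineConfig:
    seed: int
    # cohort simulation
    n_samples: int = 129
    n_genes: int = 12000
    n_duplicates: int = 12
    noise_sd: float = 1.0
    planted: list[dict] = field(
        default_factory=lambda: [
            {"fraction_g1": 33 / 129, "module_size": 100, "effect": 2.5},
            {"fraction_g1": 46 / 129, "module_size": 100, "effect": 2.5},
            {"fraction_g1": 0.30, "module_size": 100, "effect": 2.5},
            {"fraction_g1": 0.42, "module_size": 100, "effect": 2.5},
        ]
    )
    n_mirna: int = 743
    mirna_informative: int = 40
    mirna_effect: float = 2.0
    hr: float = 1.3
    baseline_rate: float = 0.1
    censor_frac: float = 0.3
    # preprocessing
    k_filter: int = 1000
    dup_quantile: float = 0.75
    n_train: int = 82
    # discovery
    m: int = 100
    max_splits: int = 6
    n_perm: int = 99
    alpha: float = 0.05
    refine_top: int = 25
    # stability
    n_boot: int = 100
    train_fraction: float = 0.63
    stability_threshold: float = 0.95
    # miRNA validation
    outer_k: int = 10
    inner_k: int = 5
    n_delta: int = 30
    # scoring
    scale_q: float = 0.025
    k_max: int = 5
    # enrichment
    fdr: float = 0.10
    gmt_path: str | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config must set an explicit seed")
        self.seed = int(self.seed)

    def stage_seed(self, stage: str) -> int:
        return (self.seed + _STAGE_OFFSETS[stage]) % (2**31)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config file must set an explicit seed")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_samples=self.n_samples,
            n_genes=self.n_genes,
            n_duplicates=self.n_duplicates,
            planted_splits=[PlantedSplit(**p) for p in self.planted],
            noise_sd=self.noise_sd,
            n_mirna=self.n_mirna,
            mirna_informative=self.mirna_informative,
            mirna_effect=self.mirna_effect,
            hr=self.hr,
            baseline_rate=self.baseline_rate,
            censor_frac=self.censor_frac,
            seed=self.stage_seed("simulate"),
        )


def _contingency(calls: pd.Series, categories: pd.Series) -> pd.DataFrame:
    tab = pd.crosstab(calls, categories)
    order = [c for c in ("angiogenic", "non-angiogenic") if c in tab.index]
    return tab.loc[order]


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage on a simulated cohort and write all artifacts under
    ``outdir``. Returns the result bundle as a dict (also written as JSON).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("simulate")
        cohort = generate_cohort(config.cohort_spec())
        write_expression(cohort.expression, outdir / "expression.tsv")
        write_expression(cohort.mirna, outdir / "mirna.tsv")
        write_duplicate_pairs(cohort.duplicate_pairs, outdir / "duplicate_pairs.tsv")
        pheno = pd.concat([cohort.survival, cohort.clinical, cohort.truth_labels], axis=1)
        write_phenotype(pheno, outdir / "phenotype.tsv")

        stage("preprocess")
        expr = vst_surrogate(cohort.expression, raw_scale=False)
        expr = quantile_normalize(expr)
        keep = filter_variable_genes(expr, k=config.k_filter, dup_quantile=config.dup_quantile)
        filtered = expr.subset_genes(keep)
        write_expression(filtered, outdir / "filtered.tsv")
        unique = cohort.unique_samples
        train_ids, model_ids = split_train_model_selection(
            unique, n_train=config.n_train, seed=config.stage_seed("split")
        )
        train = filtered.subset_samples(train_ids)
        model_sel = filtered.subset_samples(model_ids)

        stage("discover")
        splits = search_splits(
            train, m=config.m, max_splits=config.max_splits,
            n_perm=config.n_perm, alpha=config.alpha,
            seed=config.stage_seed("discover"), refine_top=config.refine_top,
        )
        write_json({f"S{i + 1}": bp.to_dict() for i, bp in enumerate(splits)},
                   outdir / "splits.json")
        bundle["n_discovered"] = len(splits)

        stage("stability")
        stables = bootstrap_stability(
            train, splits, n_boot=config.n_boot,
            train_fraction=config.train_fraction,
            seed=config.stage_seed("stability"), m=config.m,
        )
        retained = retain_stable(stables, threshold=config.stability_threshold)
        confirmed = confirm_on_holdout(
            retained, train, model_sel, n_boot=config.n_boot,
            threshold=config.stability_threshold, seed=config.stage_seed("confirm"),
            m=config.m,
        )
        write_json({f"S{i + 1}": st.to_dict() for i, st in enumerate(confirmed)},
                   outdir / "stable.json")
        bundle["n_retained"] = len(retained)
        bundle["n_confirmed"] = len(confirmed)
        bundle["stabilities"] = [st.stability for st in stables]

        if not confirmed:
            bundle["note"] = "no confirmed splits; downstream stages skipped"
            write_json(bundle, outdir / "results.json")
            _write_manifest(config, outdir)
            return bundle

        # full-cohort labels for each confirmed split via its discriminant
        stage("mirna")
        mirna_tables = {}
        full = filtered.subset_samples(unique)
        for i, st in enumerate(confirmed):
            model = lda_train(train, st.base)
            labels, _ = lda_predict(model, full)
            labels = labels.map({0: "g0", 1: "g1"})
            conf, errors, consensus = nested_cv(
                cohort.mirna, labels, outer_k=config.outer_k,
                inner_k=config.inner_k, n_delta=config.n_delta,
                seed=config.stage_seed("mirna") + i,
            )
            mirna_tables[f"S{i + 1}"] = {
                "confusion": {str(r): {str(c): int(conf.loc[r, c]) for c in conf.columns}
                              for r in conf.index},
                "per_class_error": {str(k): float(v) for k, v in errors.items()},
                "n_consensus_features": len(consensus),
            }
        write_json(mirna_tables, outdir / "mirna_validation.json")
        bundle["mirna"] = mirna_tables

        stage("score")
        # subtype of interest: the confirmed split best supported by the
        # independent microRNA layer (lowest mean per-class CV error)
        mean_err = {
            name: sum(v["per_class_error"].values()) / len(v["per_class_error"])
            for name, v in mirna_tables.items()
        }
        lead_name = min(mean_err, key=mean_err.get)
        lead = confirmed[int(lead_name[1:]) - 1].base
        bundle["lead_split"] = lead_name
        weights = lead.weights
        scaled = robust_scale(filtered.subset_samples(unique), q=config.scale_q)
        scores = signature_score(scaled, weights)
        best_k, fits = gmm_bic(scores, k_max=config.k_max,
                               seed=config.stage_seed("gmm"))
        scored = classify_subtype(scores, fits[best_k])
        scored.to_frame().to_csv(outdir / "scores.tsv", sep="\t")
        bundle["best_k"] = best_k
        bundle["score_boundary"] = scored.boundary

        stage("associate")
        clinical = {}
        if scored.calls is not None:
            surv = cohort.survival.copy()
            surv["group"] = scored.calls.reindex(surv.index).map(
                {"non-angiogenic": 0, "angiogenic": 1})
            _, lr_stat, lr_p = km_logrank(surv)
            hr, ci, cox_p = cox_hr(surv)
            clinical["logrank_p"] = lr_p
            clinical["hr"] = hr
            clinical["hr_ci"] = list(ci)
            clinical["cox_p"] = cox_p
            for covar in ("grade", "stage", "debulking"):
                tab = _contingency(scored.calls, cohort.clinical[covar])
                if tab.shape[0] == 2:
                    clinical[f"fisher_{covar}_p"] = fisher_exact(
                        tab, seed=config.stage_seed("fisher")
                    )
                    clinical[f"pct_angiogenic_by_{covar}"] = {
                        str(c): (None if pd.isna(v) else float(v))
                        for c, v in subtype_proportions(tab).items()
                    }
        write_json(clinical, outdir / "clinical.json")
        bundle["clinical"] = clinical

        stage("enrich")
        universe = filtered.genes
        if config.gmt_path:
            sets = read_gmt(config.gmt_path)
        else:
            # diagnostic gene sets: the planted modules restricted to the universe
            sets = {
                name: {"description": "planted module", "genes": genes}
                for name, genes in cohort.modules.items()
                if set(genes) & set(universe)
            }
        if sets:
            enr = hypergeom_enrich(set(lead.module) & set(universe), sets, universe,
                                   fdr=config.fdr)
            enr.to_csv(outdir / "enrichment.tsv", sep="\t")
            bundle["enriched_sets"] = list(enr.index[enr["significant"]])
    except Exception as exc:
        log.error("pipeline failed: %s", exc)
        raise

    write_json(bundle, outdir / "results.json")
    _write_manifest(config, outdir)
    return bundle


def _write_manifest(config: PipelineConfig, outdir: Path) -> None:
    import numpy, pandas, scipy, sklearn  # noqa: PLC0415

    write_json(
        {
            "risis_version": __version__,
            "numpy": numpy.__version__,
            "pandas": pandas.__version__,
            "scipy": scipy.__version__,
            "sklearn": sklearn.__version__,
            "config": dataclasses.asdict(config),
            "stage_seeds": {k: config.stage_seed(k) for k in _STAGE_OFFSETS},
        },
        outdir / "manifest.json",
    )
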