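# risis

Robust binary class discovery and portable subtype scoring for tumor
expression cohorts.

## The problem

Unsupervised subtyping of bulk tumor expression data is notoriously fragile:
clusterings driven by global expression similarity often fail to validate in
independent cohorts. `risis` implements an alternative strategy for
high-grade serous ovarian cancer-style cohorts (a single histology, ~130
tumors, ~12,000 genes, a parallel microRNA layer, survival follow-up):

1. **Discovery.** Search for *binary partitions with clear separation* — a
   bipartition of the samples is scored by its ``m`` = 100 most
   discriminating genes (its *module*),

   `t_g = (x̄_g1 − x̄_g0) / √((s²_g + s₀)(1/n₁ + 1/n₀))`,  `score = (1/m) Σ_module t_g²`,

   where `s²_g` is the pooled within-class variance and `s₀` a variance
   floor. Candidates seeded from principal-component 2-means and per-gene
   largest-gap splits are hill-climbed by single-sample reassignment and
   tested against a permutation null that re-runs the whole search on
   gene-wise shuffled data — so the selection bias of the search is in the
   null. If nothing survives, the method reports *no subtypes*, which is a
   valid answer.
2. **Stability gating.** Each candidate partition is re-discovered on random
   63% training subsets; matched rediscoveries train diagonal linear
   discriminants whose held-out predictions must agree with the candidate
   labels >95% of the time ("classification stability"). Survivors are
   re-confirmed the same way against a disjoint model-selection sample set.
3. **Cross-omics confirmation.** A nearest-shrunken-centroid classifier with
   nested cross-validation (outer folds for the unbiased error, inner folds
   for the shrinkage Δ) tests whether microRNA profiles predict each
   partition; the partition with the strongest microRNA support is the
   *angiogenic* subtype.
4. **Portable scoring.** The subtype's 100-gene module and discriminant
   weights travel to any platform: per-gene robust rescaling to [−1, 1]
   (2.5%/97.5% quantile clipping), then
   `score_s = Σ w_g x_gs / Σ |w_g|`. Bimodality of the score distribution is
   assessed with univariate Gaussian mixtures chosen by BIC
   (`−2·loglik + (3k−1)·ln n`), and samples favoring the upper component are
   called angiogenic.
5. **Clinical association.** Kaplan–Meier/logrank and Cox proportional
   hazards (Efron ties) for survival; Fisher exact tests (exact 2×2,
   fixed-margin Monte Carlo for r×c) and per-category subtype proportions
   for grade, stage and debulking.

Because the original microarray cohort is not bundled, the package ships a
first-class synthetic-cohort generator (`risis.synthetic`) that emulates the
study design — 129 tumors with 12 technical duplicates, four planted
partitions each carried by a disjoint 100-gene module, 743 microRNAs
tracking the first partition, exponential survival with a subtype hazard
ratio — so every stage is testable end to end against known ground truth.

## Worked example

The numbered drivers under `analysis/` run the whole study shape on a
simulated cohort (about four minutes total; artifacts land in
`results/analysis/`):

```bash
python analysis/01_simulate.py
python analysis/02_preprocess.py
python analysis/03_discover.py
python analysis/04_stability.py
python analysis/05_mirna_validate.py
python analysis/06_score.py
python analysis/07_clinical.py
python analysis/08_enrichment.py
```

Selected output from one run (seed 20260930):

```
found 4 significant partition(s) of 82 training samples
  S1: score=45.1 p=0.01 minority=35 -> planted S4 agreement 1.00
  ...
training stability (n_boot=100):
  S1: stability=1.000 matched=1.00 -> retained
  S4: stability=0.988 matched=0.74 -> retained
4 of 4 retained split(s) confirmed on the model-selection samples
split 4: miRNA nested-CV per-class errors g0=0.000, g1=0.000; 31 consensus microRNAs
lead split: S4 (mean miRNA CV error 0.000)
BIC by component count: k=1: 117.7, k=2: -315.0, k=3: -300.8, ...
chosen k = 2
calls: 33 angiogenic / 96 non-angiogenic (boundary score 0.070)
Cox HR (angiogenic vs non-angiogenic) = 1.17 [0.73, 1.88], logrank p = 0.516
```

Reading: all four planted partitions are recovered exactly and pass the 95%
stability bar; only the partition with planted microRNA support survives
cross-omics validation with low error, its score distribution is bimodal
(k = 2 by BIC), the 33 called angiogenic tumors coincide with the planted
minority, and the hazard-ratio estimate brackets the simulated 1.3 — not
significant at n = 129, as expected for this effect size.

The same stages are scriptable via the `risis` console command
(`simulate`, `preprocess`, `discover`, `stability`, `mirna-validate`,
`score`, `associate`, `enrich`, `run-all`) or the `run_pipeline` API.

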