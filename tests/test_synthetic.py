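"""Generator contracts: determinism, planted structure, survival and miRNA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from risis.synthetic import (
    CohortSpec,
    PlantedSplit,
    generate_cohort,
    generate_mirna,
    generate_survival,
)


def _spec(**kw):
    base = dict(n_samples=60, n_genes=1500, n_duplicates=6, seed=5,
                planted_splits=[PlantedSplit(fraction_g1=0.3, module_size=50, effect=2.5)])
    base.update(kw)
    return CohortSpec(**base)


class TestGenerateCohort:
    def test_default_spec_dimensions(self):
        cohort = generate_cohort(CohortSpec(seed=1))
        assert cohort.expression.shape == (12000, 129 + 12)
        assert len(cohort.unique_samples) == 129
        assert len(cohort.duplicate_pairs) == 12
        modules = list(cohort.modules.values())
        assert [len(m) for m in modules] == [100, 100, 100, 100]
        # modules are pairwise disjoint
        all_genes = [g for m in modules for g in m]
        assert len(all_genes) == len(set(all_genes))
        assert cohort.mirna.shape == (743, 129)

    def test_same_seed_bit_identical_different_seed_not(self):
        a = generate_cohort(_spec())
        b = generate_cohort(_spec())
        c = generate_cohort(_spec(seed=6))
        pd.testing.assert_frame_equal(a.expression.values, b.expression.values)
        pd.testing.assert_frame_equal(a.survival, b.survival)
        assert not np.allclose(a.expression.values, c.expression.values)

    def test_no_planted_splits_null_t_rejection_rate(self):
        cohort = generate_cohort(_spec(planted_splits=[], n_genes=3000))
        X = cohort.expression.values[cohort.unique_samples].to_numpy()
        rng = np.random.default_rng(0)
        lab = rng.permutation([0] * 30 + [1] * 30)
        _, p = stats.ttest_ind(X[:, lab == 1], X[:, lab == 0], axis=1)
        rate = (p < 0.05).mean()
        assert 0.03 < rate < 0.07

    def test_planted_separation_matches_effect(self):
        spec = _spec(n_samples=100, planted_splits=[
            PlantedSplit(fraction_g1=0.4, module_size=100, effect=3.0)])
        cohort = generate_cohort(spec)
        lab = cohort.truth_labels["S1"].to_numpy()
        M = cohort.expression.values.loc[
            cohort.modules["S1"], cohort.unique_samples].to_numpy()
        sep = (M[:, lab == 1].mean(axis=1) - M[:, lab == 0].mean(axis=1)).mean()
        assert sep == pytest.approx(3.0, abs=0.15)

    def test_duplicates_correlate_more_than_random_pairs(self):
        cohort = generate_cohort(_spec(planted_splits=[
            PlantedSplit(fraction_g1=0.3, module_size=200, effect=3.0)]))
        vals = cohort.expression.values
        dup_corr = np.mean([vals[a].corr(vals[b]) for a, b in cohort.duplicate_pairs])
        rng = np.random.default_rng(1)
        uniq = cohort.unique_samples
        rand_pairs = [(uniq[i], uniq[j]) for i, j in
                      rng.choice(len(uniq), size=(30, 2), replace=True) if i != j]
        rand_corr = np.mean([vals[a].corr(vals[b]) for a, b in rand_pairs])
        assert dup_corr > rand_corr

    def test_duplicate_pairs_share_truth_labels(self):
        cohort = generate_cohort(_spec())
        for a, b in cohort.duplicate_pairs:
            assert a in cohort.truth_labels.index
            assert b.endswith("-dup")

    def test_oversized_modules_rejected(self):
        with pytest.raises(ValueError, match="n_genes"):
            CohortSpec(n_genes=100, seed=0, planted_splits=[
                PlantedSplit(fraction_g1=0.3, module_size=60),
                PlantedSplit(fraction_g1=0.2, module_size=60)])

    @pytest.mark.parametrize("bad", [0.0, 0.5, 0.9])
    def test_minority_fraction_bounds(self, bad):
        with pytest.raises(ValueError):
            PlantedSplit(fraction_g1=bad)


class TestGenerateSurvival:
    def test_null_logrank_p_uniform(self):
        from risis.survival import km_logrank

        rng = np.random.default_rng(3)
        labels = pd.Series([0] * 50 + [1] * 50)
        ps = []
        for _ in range(200):
            surv = generate_survival(labels, hr=1.0, baseline_rate=0.1,
                                     censor_frac=0.2, seed=int(rng.integers(2**31)))
            ps.append(km_logrank(surv)[2])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_cox_ci_coverage_at_study_scale(self):
        from risis.survival import cox_hr

        rng = np.random.default_rng(4)
        labels = pd.Series([0] * 720 + [1] * 370)  # ~ validation-cohort split
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            surv = generate_survival(labels, hr=1.3, baseline_rate=0.1,
                                     censor_frac=0.3, seed=int(rng.integers(2**31)))
            _, (lo, hi), _ = cox_hr(surv)
            hits += lo <= 1.3 <= hi
        assert hits >= 93

    def test_censoring_fraction_approximate(self):
        labels = pd.Series([0] * 500 + [1] * 250)
        surv = generate_survival(labels, hr=1.3, baseline_rate=0.2,
                                 censor_frac=0.4, seed=9)
        frac_censored = 1.0 - surv["event"].mean()
        assert frac_censored == pytest.approx(0.4, abs=0.08)

    def test_degenerate_inputs_rejected(self):
        labels = pd.Series([0] * 5 + [1] * 5)
        with pytest.raises(ValueError):
            generate_survival(labels, hr=1.0, baseline_rate=0.0)
        with pytest.raises(ValueError):
            generate_survival(labels, hr=-1.0, baseline_rate=0.1)
        with pytest.raises(ValueError):
            generate_survival(pd.Series([0] * 10), hr=1.0, baseline_rate=0.1)


class TestGenerateMirna:
    def test_feature_ids_and_shape(self):
        spec = _spec()
        lab = pd.Series([0] * 40 + [1] * 20, index=[f"x{i}" for i in range(60)])
        mat = generate_mirna(lab, spec, seed=1)
        assert mat.shape == (spec.n_mirna, 60)
        assert mat.genes[0] == "mir0001"
        assert mat.genes[-1] == f"mir{spec.n_mirna:04d}"

    def test_informative_features_shifted(self):
        spec = _spec(mirna_informative=30, mirna_effect=4.0)
        lab = pd.Series([0] * 40 + [1] * 20, index=[f"x{i}" for i in range(60)])
        mat = generate_mirna(lab, spec, seed=1)
        X = mat.values.to_numpy()
        shift = X[:30, 40:].mean() - X[:30, :40].mean()
        assert shift == pytest.approx(4.0, abs=0.5)
        null_shift = X[30:, 40:].mean() - X[30:, :40].mean()
        assert abs(null_shift) < 0.3

    def test_too_many_informative_rejected(self):
        with pytest.raises(ValueError, match="mirna_informative"):
            _spec(n_mirna=10, mirna_informative=20)
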