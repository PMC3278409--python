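"""Partition search: scoring, refinement, discriminant training/prediction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from risis.io import ExpressionMatrix
from risis.isis import (
    _variance_floor,
    label_agreement,
    lda_predict,
    lda_train,
    search_splits,
    split_score,
)


class TestSplitScore:
    def test_symmetric_under_label_swap(self, toy_matrix):
        lab = np.array([0, 0, 0, 1, 1, 1, 0, 1])
        s1, m1 = split_score(toy_matrix, lab, m=5)
        s2, m2 = split_score(toy_matrix, 1 - lab, m=5)
        assert s1 == pytest.approx(s2, rel=1e-12)
        assert m1 == m2

    def test_invariant_to_gene_and_sample_permutation(self, toy_matrix):
        rng = np.random.default_rng(0)
        lab = np.array([0, 0, 0, 1, 1, 1, 0, 1])
        base, _ = split_score(toy_matrix, lab, m=5)
        gperm = rng.permutation(toy_matrix.genes)
        sperm = rng.permutation(len(lab))
        shuffled = ExpressionMatrix(
            toy_matrix.values.loc[gperm].iloc[:, sperm]
        )
        score, _ = split_score(shuffled, lab[sperm], m=5)
        assert score == pytest.approx(base, rel=1e-10)

    def test_module_size_contract(self, small_filtered):
        rng = np.random.default_rng(1)
        lab = rng.permutation([1] * 30 + [0] * 50)
        _, module = split_score(small_filtered, lab, m=100)
        assert len(module) == 100

    def test_planted_labels_beat_random_draws(self, small_cohort, small_filtered):
        truth = small_cohort.truth_labels["S1"].to_numpy()
        s0 = _variance_floor(small_filtered.values.to_numpy())
        planted, _ = split_score(small_filtered, truth, m=60, s0=s0)
        rng = np.random.default_rng(2)
        best_random = max(
            split_score(small_filtered, rng.permutation(truth), m=60, s0=s0)[0]
            for _ in range(100)
        )
        assert planted > best_random

    def test_tiny_class_rejected(self, toy_matrix):
        with pytest.raises(ValueError):
            split_score(toy_matrix, np.array([1, 0, 0, 0, 0, 0, 0, 0]), m=5)


class TestSearchSplits:
    def test_exhaustive_oracle_on_toys(self):
        """The refined search must match brute-force enumeration of all
        bipartitions of 8 samples (within 1e-9)."""
        rng = np.random.default_rng(0)
        for trial in range(6):
            X = rng.normal(0, 1, size=(12, 8))
            if trial % 2 == 0:
                X[:4, :3] += 1.5
            mat = ExpressionMatrix(pd.DataFrame(
                X, index=[f"g{i}" for i in range(12)],
                columns=[f"s{j}" for j in range(8)]))
            s0 = _variance_floor(X)
            best_brute = -1.0
            for bits in itertools.product([0, 1], repeat=7):
                lab = np.array((0,) + bits)
                if min(lab.sum(), 8 - lab.sum()) < 2:
                    continue
                sc, _ = split_score(mat, lab, m=5, s0=s0)
                best_brute = max(best_brute, sc)
            found = search_splits(mat, m=5, min_group_size=2, n_perm=0, max_splits=1)
            assert found, "search returned nothing on a toy"
            assert found[0].score >= best_brute - 1e-9

    def test_recovers_planted_split(self, small_cohort, small_filtered):
        splits = search_splits(small_filtered, m=60, n_perm=49, seed=3)
        assert len(splits) >= 1
        truth = small_cohort.truth_labels["S1"]
        assert label_agreement(splits[0].labels.reindex(truth.index), truth) >= 0.95
        assert splits[0].pvalue < 0.05
        assert splits[0].n_g1 <= len(truth) - splits[0].n_g1

    def test_deterministic_given_seed(self, small_filtered):
        a = search_splits(small_filtered, m=60, n_perm=39, seed=9)
        b = search_splits(small_filtered, m=60, n_perm=39, seed=9)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            pd.testing.assert_series_equal(x.labels, y.labels)
            assert x.score == y.score and x.pvalue == y.pvalue

    def test_infeasible_min_group_size(self, toy_matrix):
        with pytest.raises(ValueError, match="min_group_size"):
            search_splits(toy_matrix, min_group_size=5, n_perm=0)


class TestDiagonalLDA:
    def _split(self, matrix, labels, m=60):
        from risis.isis import Bipartition, _tstats

        X = matrix.values.to_numpy()
        s0 = _variance_floor(X)
        score, module = split_score(matrix, labels, m=m, s0=s0)
        t = _tstats(X, np.asarray(labels), s0)
        pos = {g: i for i, g in enumerate(matrix.genes)}
        return Bipartition(
            labels=pd.Series(labels, index=matrix.samples),
            module=module,
            t_stats=pd.Series({g: t[pos[g]] for g in module}),
            score=score,
        )

    def test_separated_classes_zero_training_error(self, small_cohort, small_filtered):
        truth = small_cohort.truth_labels["S1"]
        bp = self._split(small_filtered, truth.to_numpy())
        model = lda_train(small_filtered, bp)
        pred, proj = lda_predict(model, small_filtered)
        assert label_agreement(pred, truth) == 1.0

    def test_weight_signs_match_mean_differences(self, small_cohort, small_filtered):
        truth = small_cohort.truth_labels["S1"].to_numpy()
        bp = self._split(small_filtered, truth)
        model = lda_train(small_filtered, bp)
        M = small_filtered.values.loc[model.genes]
        diff = M.loc[:, truth == 1].mean(axis=1) - M.loc[:, truth == 0].mean(axis=1)
        assert (np.sign(model.weights) == np.sign(diff)).all()

    def test_heldout_accuracy_on_fresh_noise(self, small_cohort, small_filtered):
        """Duplicates are re-noised copies of training samples: prediction on
        them must agree with the source sample's class."""
        truth = small_cohort.truth_labels["S1"]
        bp = self._split(small_filtered, truth.to_numpy())
        model = lda_train(small_filtered, bp)
        from risis.preprocess import quantile_normalize

        full = quantile_normalize(small_cohort.expression)
        dup_ids = [b for _, b in small_cohort.duplicate_pairs]
        dup = full.subset_genes(small_filtered.genes).values[dup_ids]
        pred, _ = lda_predict(model, dup)
        expected = truth.loc[[a for a, _ in small_cohort.duplicate_pairs]]
        acc = (pred.to_numpy() == expected.to_numpy()).mean()
        assert acc >= 0.9

    def test_missing_genes_renormalized(self, small_cohort, small_filtered):
        truth = small_cohort.truth_labels["S1"]
        bp = self._split(small_filtered, truth.to_numpy())
        model = lda_train(small_filtered, bp)
        rng = np.random.default_rng(7)
        keep = list(rng.choice(model.genes, size=len(model.genes) // 2, replace=False))
        reduced = small_filtered.values.loc[keep]
        with pytest.warns(UserWarning, match="missing"):
            pred, _ = lda_predict(model, reduced)
        assert label_agreement(pred, truth) >= 0.8

    def test_all_genes_missing_is_error(self, small_cohort, small_filtered):
        truth = small_cohort.truth_labels["S1"]
        bp = self._split(small_filtered, truth.to_numpy())
        model = lda_train(small_filtered, bp)
        other = small_filtered.values.copy()
        other.index = [f"zz{i}" for i in range(len(other.index))]
        with pytest.raises(ValueError, match="no module genes"):
            lda_predict(model, other)


def test_label_agreement_class_matching():
    a = [0, 0, 1, 1]
    assert label_agreement(a, [1, 1, 0, 0]) == 1.0
    assert label_agreement(a, [0, 0, 1, 0]) == 0.75
    with pytest.raises(ValueError):
        label_agreement([], [])
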