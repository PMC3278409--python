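"""Signature scoring, robust scaling, mixture/BIC bimodality and calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from risis.io import ExpressionMatrix
from risis.scoring import (
    classify_subtype,
    gmm_bic,
    map_genes,
    robust_scale,
    signature_score,
)


def _df(arr, genes=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=genes, columns=[f"s{j}" for j in range(arr.shape[1])])


class TestMapGenes:
    def test_identity_map_unchanged(self):
        df = _df(np.arange(12).reshape(3, 4))
        out = map_genes(df, {g: g for g in df.index})
        pd.testing.assert_frame_equal(out, df)

    def test_higher_variance_probe_wins(self):
        df = _df([[1, 1, 1, 1.1], [0, 5, -5, 10]], genes=["pA", "pB"])
        out = map_genes(df, {"pA": "GENE", "pB": "GENE"})
        np.testing.assert_allclose(out.loc["GENE"], df.loc["pB"])

    def test_no_mappable_probes_rejected(self):
        df = _df(np.ones((2, 3)))
        with pytest.raises(ValueError):
            map_genes(df, {"unrelated": "GENE"})


class TestRobustScale:
    def test_constant_gene_maps_to_zero(self):
        out = robust_scale(_df([[5, 5, 5, 5], [1, 2, 3, 4]]), q=0.1)
        assert (out.iloc[0] == 0).all()

    def test_clip_quantiles_map_to_extremes(self):
        x = np.arange(1, 101, dtype=float)[None, :]
        out = robust_scale(_df(x), q=0.025).to_numpy()[0]
        assert out.min() == -1.0 and out.max() == 1.0
        # interior values strictly inside
        assert (np.abs(out[5:-5]) < 1.0).all()

    @settings(max_examples=25, deadline=None)
    @given(
        slope=st.floats(0.1, 50.0),
        offset=st.floats(-100.0, 100.0),
    )
    def test_invariant_to_positive_affine_transforms(self, slope, offset):
        rng = np.random.default_rng(0)
        base = _df(rng.normal(0, 1, size=(5, 40)))
        a = robust_scale(base, q=0.05).to_numpy()
        b = robust_scale(base * slope + offset, q=0.05).to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_q_bounds(self):
        with pytest.raises(ValueError):
            robust_scale(_df(np.ones((2, 5))), q=0.5)
        with pytest.raises(ValueError):
            robust_scale(_df(np.ones((2, 2))), q=0.1)


class TestSignatureScore:
    def test_extreme_case_scores_one(self):
        df = _df(np.ones((3, 4)))
        w = pd.Series([0.5, 1.0, 2.0], index=df.index)
        assert (signature_score(df, w) == 1.0).all()

    def test_antisymmetric_in_weights(self):
        rng = np.random.default_rng(1)
        df = _df(rng.uniform(-1, 1, size=(6, 10)))
        w = pd.Series(rng.normal(size=6), index=df.index)
        np.testing.assert_allclose(
            signature_score(df, w), -signature_score(df, -w), atol=1e-12)

    def test_missing_genes_excluded_from_both_sums(self):
        df = _df(np.ones((2, 3)), genes=["a", "b"])
        w = pd.Series({"a": 1.0, "b": 1.0, "zz": 100.0})
        assert (signature_score(df, w) == 1.0).all()
        with pytest.raises(ValueError):
            signature_score(df, pd.Series({"zz": 1.0}))

    def test_separation_grows_with_effect(self):
        from risis.preprocess import filter_variable_genes, quantile_normalize
        from risis.synthetic import CohortSpec, PlantedSplit, generate_cohort

        margins = []
        for effect in (1.0, 3.0):
            spec = CohortSpec(n_samples=60, n_genes=1000, n_duplicates=0,
                              planted_splits=[PlantedSplit(0.3, 50, effect)], seed=13)
            cohort = generate_cohort(spec)
            filt = quantile_normalize(cohort.expression)
            scaled = robust_scale(filt.subset_genes(cohort.modules["S1"]))
            w = pd.Series(1.0, index=cohort.modules["S1"])
            scores = signature_score(scaled, w)
            lab = cohort.truth_labels["S1"].to_numpy()
            margins.append(scores[lab == 1].mean() - scores[lab == 0].mean())
        assert margins[1] > margins[0] > 0


class TestGmmBic:
    def test_unimodal_prefers_one_component(self):
        rng = np.random.default_rng(2)
        k, fits = gmm_bic(rng.normal(0, 1, 1000), seed=0)
        assert k == 1

    def test_bimodal_prefers_two_components(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(-2, 1, 600), rng.normal(2, 1, 400)])
        k, fits = gmm_bic(x, seed=0)
        assert k == 2
        means = np.sort(fits[2].means)
        assert means == pytest.approx([-2, 2], abs=0.3)

    def test_loglik_monotone_across_em_iterations(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(-1, 1, 300), rng.normal(2, 0.5, 200)])
        _, fits = gmm_bic(x, seed=1)
        for fit in fits.values():
            trace = np.asarray(fit.loglik_trace)
            assert (np.diff(trace) >= -1e-7).all()

    def test_agrees_with_sklearn_mixture(self):
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(-2, 0.8, 400), rng.normal(1.5, 0.6, 300)])
        _, fits = gmm_bic(x, seed=2)
        sk = GaussianMixture(2, n_init=5, random_state=0).fit(x[:, None])
        ours = np.sort(fits[2].means)
        theirs = np.sort(sk.means_.ravel())
        np.testing.assert_allclose(ours, theirs, atol=0.05)
        assert fits[2].loglik == pytest.approx(sk.score(x[:, None]) * x.size, rel=1e-3)

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError):
            gmm_bic(np.zeros(10))
        with pytest.raises(ValueError):
            gmm_bic(np.random.default_rng(0).normal(size=19), k_max=5)


class TestClassifySubtype:
    def test_symmetric_mixture_boundary_at_midpoint(self):
        from risis.scoring import MixtureFit

        mixture = MixtureFit(
            k=2, weights=np.array([0.5, 0.5]), means=np.array([-2.0, 2.0]),
            variances=np.array([1.0, 1.0]), loglik=0.0, bic=0.0)
        rng = np.random.default_rng(6)
        scores = pd.Series(np.concatenate(
            [rng.normal(-2, 1, 500), rng.normal(2, 1, 500)]))
        result = classify_subtype(scores, mixture)
        assert result.boundary == pytest.approx(0.0, abs=0.01)
        # a score at the upper component's mean is called angiogenic
        probe = classify_subtype(pd.Series([2.0]), mixture)
        assert probe.calls.iloc[0] == "angiogenic"

    def test_single_component_returns_no_subtype_flag(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=200)
        _, fits = gmm_bic(x, seed=0)
        result = classify_subtype(pd.Series(x), fits[1])
        assert result.calls is None and result.boundary is None
        assert (result.to_frame()["call"] == "no-subtype").all()

    def test_end_to_end_recovery_of_planted_minority(self, small_cohort, small_filtered):
        from risis.isis import label_agreement, lda_train, search_splits

        splits = search_splits(small_filtered, m=60, n_perm=0, seed=0, max_splits=1)
        scaled = robust_scale(small_filtered)
        scores = signature_score(scaled, splits[0].weights)
        k, fits = gmm_bic(scores, seed=3)
        assert k >= 2
        result = classify_subtype(scores, fits[k])
        calls = result.calls.map({"angiogenic": 1, "non-angiogenic": 0})
        truth = small_cohort.truth_labels["S1"].reindex(calls.index)
        assert label_agreement(calls, truth) >= 0.9
        # upper-component weight approximates the planted minority fraction
        upper = int(np.argmax(fits[k].means))
        assert fits[k].weights[upper] == pytest.approx(0.30, abs=0.1)
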