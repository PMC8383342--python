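"""Hellinger/RDA/permutation/Spearman machinery and the niche rule set."""

import numpy as np
import pandas as pd
import pytest

from phycotad.abundance import AbundanceMatrix, PatternClusters
from phycotad.niche import (CorrelationResult, DiatomCountTable, classify,
                            export_network, flag_dominants, hellinger,
                            permutation_test, rda, spearman_matrix,
                            spearman_pair)


def _diatoms(counts: dict, years=None) -> DiatomCountTable:
    df = pd.DataFrame(counts)
    if years is None:
        years = pd.Series(2010, index=df.columns)
    return DiatomCountTable(counts=df, sample_year=years,
                            dominants=flag_dominants(df, years))


class TestHellinger:
    def test_single_species_sample(self):
        out = hellinger(pd.DataFrame({"s1": [1.0, 0.0, 0.0]}))
        assert out.loc["s1"].tolist() == pytest.approx([1.0, 0.0, 0.0])

    def test_uniform_sample(self):
        out = hellinger(pd.DataFrame({"s1": [1.0, 1.0, 1.0, 1.0]}))
        assert out.loc["s1"].tolist() == pytest.approx([0.5] * 4)

    def test_rows_have_unit_sum_of_squares(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.uniform(0, 100, size=(6, 10)))
        out = hellinger(df)
        assert np.allclose((out ** 2).sum(axis=1), 1.0, atol=1e-9)

    def test_negative_rejected_and_empty_flagged(self):
        with pytest.raises(ValueError):
            hellinger(pd.DataFrame({"s1": [-1.0]}))
        out = hellinger(pd.DataFrame({"s1": [1.0], "s2": [0.0]}))
        assert np.isnan(out.loc["s2"]).all()


class TestRDA:
    def test_perfect_linear_fit(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(15, 2)))
        B = rng.normal(size=(2, 4))
        Y = pd.DataFrame(X.to_numpy() @ B)
        assert rda(Y, X).r2 == pytest.approx(1.0)

    def test_single_predictor_equals_squared_pearson(self):
        rng = np.random.default_rng(4)
        Y = pd.DataFrame(rng.normal(size=(25, 1)))
        X = pd.DataFrame(rng.normal(size=(25, 1)))
        r = np.corrcoef(Y[0], X[0])[0, 1]
        assert abs(rda(Y, X).r2 - r ** 2) < 1e-10

    def test_collinear_predictor_dropped_with_warning(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"a": rng.normal(size=12)})
        X["b"] = 2 * X["a"]
        Y = pd.DataFrame(rng.normal(size=(12, 3)))
        with pytest.warns(UserWarning, match="collinear"):
            res = rda(Y, X)
        assert res.n_predictors == 1
        assert len(res.dropped_predictors) == 1
        assert res.dropped_predictors[0] in {"a", "b"}

    def test_adj_r2_missing_when_saturated(self):
        rng = np.random.default_rng(6)
        Y = pd.DataFrame(rng.normal(size=(4, 2)))
        X = pd.DataFrame(rng.normal(size=(4, 3)))
        assert rda(Y, X).adj_r2 is None

    def test_null_r2_near_p_over_n_minus_1(self):
        """E[R²] ≈ p/(n−1) when X is independent of Y."""
        rng = np.random.default_rng(7)
        n, p = 40, 3
        r2s = [rda(pd.DataFrame(rng.normal(size=(n, 5))),
                   pd.DataFrame(rng.normal(size=(n, p)))).r2
               for _ in range(200)]
        assert np.mean(r2s) == pytest.approx(p / (n - 1), abs=0.02)


class TestPermutationTest:
    def test_minimum_p_is_add_one(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(20, 2)))
        Y = pd.DataFrame(X.to_numpy() @ rng.normal(size=(2, 5)))
        res = permutation_test(Y, X, n_perm=99, seed=0)
        assert res.perm_p == pytest.approx(1 / 100)

    def test_invariant_to_predictor_column_order(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(14, 3)), columns=list("abc"))
        Y = pd.DataFrame(rng.normal(size=(14, 4)))
        p1 = permutation_test(Y, X, n_perm=199, seed=5).perm_p
        p2 = permutation_test(Y, X[["c", "a", "b"]], n_perm=199,
                              seed=5).perm_p
        assert p1 == p2


class TestSpearman:
    def test_monotone_pair(self):
        rho, p = spearman_pair([1, 2, 3, 4, 5], [10, 20, 40, 80, 160])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 120)  # both extreme orderings

    def test_hand_example(self):
        rho, _ = spearman_pair([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)

    def test_constant_series_undefined(self):
        rho, p = spearman_pair([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)

    def test_exact_matches_t_approx_roughly(self):
        rng = np.random.default_rng(10)
        x = rng.permutation(9).astype(float)
        y = x + rng.normal(0, 2, size=9)
        rho_e, p_exact = spearman_pair(x, y, exact_max_n=9)
        rho_t, p_t = spearman_pair(x, y, exact_max_n=0)
        assert rho_e == rho_t
        assert p_exact == pytest.approx(p_t, abs=0.08)

    def test_matrix_shape_and_range(self, relabund, dataset):
        corr = spearman_matrix(relabund, dataset.diatoms)
        assert corr.rho.shape == (len(relabund.values.index),
                                  len(dataset.diatoms.species))
        assert (corr.rho.abs().le(1.0) | corr.rho.isna()).all().all()


def _corr_from(rho: dict, p: dict) -> CorrelationResult:
    return CorrelationResult(rho=pd.DataFrame(rho).T, p=pd.DataFrame(p).T)


def _clusters(mapping) -> PatternClusters:
    return PatternClusters(pd.Series(mapping), None)


class TestClassify:
    def test_positive_and_fluctuating_is_colonizer(self):
        corr = _corr_from({"m1": {"d1": 0.9}}, {"m1": {"d1": 0.01}})
        labels = classify(corr, _clusters({"m1": "fluctuating"}))
        assert labels["m1"] == "colonizer"
        assert labels.rationale["m1"] == "POS_CORR"

    def test_persistent_overrides_positive_correlation(self):
        corr = _corr_from({"m1": {"d1": 0.9}}, {"m1": {"d1": 0.01}})
        labels = classify(corr, _clusters({"m1": "persistent"}))
        assert labels["m1"] == "generalist"
        assert labels.rationale["m1"] == "PERSISTENT"

    def test_negative_only_and_no_sig_rationales(self):
        corr = _corr_from(
            {"neg": {"d1": -0.9}, "none": {"d1": 0.3}},
            {"neg": {"d1": 0.01}, "none": {"d1": 0.4}})
        labels = classify(corr, _clusters({"neg": "fluctuating",
                                           "none": "fluctuating"}))
        assert labels.rationale["neg"] == "NEG_ONLY"
        assert labels.rationale["none"] == "NO_SIG"
        assert set(labels.labels) == {"generalist"}

    def test_missing_cluster_raises(self):
        corr = _corr_from({"m1": {"d1": 0.9}}, {"m1": {"d1": 0.01}})
        with pytest.raises(KeyError):
            classify(corr, _clusters({"other": "persistent"}))

    def test_recovers_planted_labels(self, dataset, niche_labels):
        truth = dataset.truth.labels
        got = niche_labels.labels.reindex(truth.index)
        assert (got == truth).all()
        # rationale codes partition the generalists
        gen_rat = niche_labels.rationale[niche_labels.generalists]
        assert set(gen_rat) <= {"PERSISTENT", "NEG_ONLY", "NO_SIG"}


class TestNetwork:
    def test_empty_edges_have_header(self):
        corr = _corr_from({"m1": {"d1": -0.5}}, {"m1": {"d1": 0.01}})
        labels = classify(corr, _clusters({"m1": "fluctuating"}))
        diatoms = _diatoms({"s1": {"d1": 5.0}, "s2": {"d1": 1.0}})
        edges = export_network(corr, labels, diatoms)
        assert edges.empty
        assert list(edges.columns) == ["mag_id", "species_id", "rho",
                                       "mag_label", "dominance_years",
                                       "significant"]

    def test_edge_count_matches_filter(self, dataset, relabund,
                                       niche_labels):
        corr = spearman_matrix(relabund, dataset.diatoms)
        edges = export_network(corr, niche_labels, dataset.diatoms)
        expected = int((corr.significant & corr.positive).sum().sum())
        assert len(edges) == expected
        assert (edges["rho"] > 0).all()

    def test_roundtrip(self, dataset, relabund, niche_labels, tmp_path):
        from phycotad.io import read_tsv, write_tsv
        corr = spearman_matrix(relabund, dataset.diatoms)
        edges = export_network(corr, niche_labels, dataset.diatoms)
        write_tsv(edges, tmp_path / "edges.tsv", index=False)
        back = read_tsv(tmp_path / "edges.tsv", index_col=None)
        assert list(back.columns) == list(edges.columns)
        assert len(back) == len(edges)
        assert back["mag_id"].tolist() == edges["mag_id"].tolist()
        assert back["species_id"].tolist() == edges["species_id"].tolist()
        assert np.allclose(back["rho"], edges["rho"])
        assert back["significant"].all()
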