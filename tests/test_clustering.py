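import itertools
import math

import numpy as np
import pytest
from sklearn.cluster import AffinityPropagation
from sklearn.metrics import adjusted_rand_score

import photoclock as pc
from photoclock.clustering import (ExpressionMatrix, affinity_propagation,
                                   filter_coherent, overlap_enrichment,
                                   preprocess, similarity)


def toy_matrix(values, n_t=4):
    n_genes = values.shape[0]
    genes = [f"g{i}" for i in range(n_genes)]
    zt = np.arange(n_t, dtype=float) * 4
    return ExpressionMatrix(genes, ["c1"], {"c1": zt}, values)


class TestPreprocess:
    def test_output_standardised_per_condition(self, planted_matrix):
        m, _, _ = planted_matrix
        out = preprocess(m)
        for sl in out.condition_slices().values():
            block = out.values[:, sl]
            assert np.allclose(block.mean(axis=1), 0, atol=1e-10)
            assert np.allclose(block.var(axis=1), 1, atol=1e-10)

    def test_constant_gene_dropped_and_logged(self, caplog):
        vals = np.vstack([np.ones(4), [0, 1, 2, 1], [2, 0, 1, 3.]])
        with caplog.at_level("INFO", logger="photoclock.clustering"):
            out = preprocess(toy_matrix(vals))
        assert out.genes == ["g1", "g2"]
        assert any("dropped" in rec.message for rec in caplog.records)

    def test_idempotent_on_retained_genes(self, planted_matrix):
        m, _, _ = planted_matrix
        once = preprocess(m)
        twice = preprocess(once)
        assert np.allclose(once.values, twice.values, atol=1e-10)

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            preprocess(toy_matrix(np.ones((3, 4))))

    def test_too_few_timepoints_rejected(self):
        m = ExpressionMatrix(["g0"], ["c"], {"c": np.array([0.0])},
                             np.array([[1.0]]))
        with pytest.raises(ValueError):
            preprocess(m)


class TestSimilarity:
    def test_identical_and_negated_profiles(self):
        base = np.array([0.0, 1, 2, 1])
        vals = np.vstack([base, base, -base])
        S = similarity(preprocess(toy_matrix(vals)))
        assert S[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert S[0, 2] == pytest.approx(-1.0, abs=1e-12)
        assert np.allclose(np.diag(S), 1.0)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(5)
        vals = rng.standard_normal((10, 8))
        m = preprocess(ExpressionMatrix(
            [f"g{i}" for i in range(10)], ["a", "b"],
            {"a": np.arange(4.0), "b": np.arange(4.0)}, vals))
        S = similarity(m)
        for i in range(10):
            for j in range(10):
                want = np.corrcoef(m.values[i], m.values[j])[0, 1]
                assert S[i, j] == pytest.approx(want, abs=1e-12)


class TestAffinityPropagation:
    def test_exact_copies_form_one_cluster(self):
        base = np.array([0.0, 1, 2, 1])
        S = similarity(preprocess(toy_matrix(np.vstack([base] * 3
                                                       + [[3, 0, -2, 5.]]))))
        res = affinity_propagation(S)
        assert res.labels[0] == res.labels[1] == res.labels[2]

    def test_planted_three_clusters_recovered(self, planted_matrix):
        m, truth, _ = planted_matrix
        mp = preprocess(m)
        res = affinity_propagation(similarity(mp))
        assert res.converged
        mask = truth >= 0
        assert adjusted_rand_score(truth[mask], res.labels[mask]) >= 0.9

    def test_deterministic_rerun(self, planted_matrix):
        m, _, _ = planted_matrix
        S = similarity(preprocess(m))
        a = affinity_propagation(S)
        b = affinity_propagation(S)
        assert np.array_equal(a.labels, b.labels)

    def test_agrees_with_sklearn_implementation(self, planted_matrix):
        # independent cross-check: same similarity, preference and damping
        m, _, _ = planted_matrix
        S = similarity(preprocess(m))
        ours = affinity_propagation(S, damping=0.9)
        off = S[~np.eye(len(S), dtype=bool)]
        sk = AffinityPropagation(affinity="precomputed", damping=0.9,
                                 preference=float(np.median(off)),
                                 max_iter=500, random_state=0).fit(S)
        assert adjusted_rand_score(sk.labels_, ours.labels) >= 0.95

    def test_label_permutation_invariance(self, planted_matrix):
        m, _, _ = planted_matrix
        S = similarity(preprocess(m))
        res = affinity_propagation(S)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(S))
        res_p = affinity_propagation(S[np.ix_(perm, perm)])
        assert adjusted_rand_score(res.labels[perm], res_p.labels) == pytest.approx(1.0)

    def test_asymmetric_similarity_rejected(self):
        S = np.array([[1.0, 0.2], [0.5, 1.0]])
        with pytest.raises(ValueError):
            affinity_propagation(S)

    def test_bad_damping_rejected(self):
        S = np.eye(3)
        with pytest.raises(ValueError):
            affinity_propagation(S, damping=0.3)


class TestFilterCoherent:
    def test_oversized_threshold_gives_empty_result(self, planted_matrix):
        m, _, _ = planted_matrix
        S = similarity(preprocess(m))
        res = affinity_propagation(S)
        out = filter_coherent(res, S, min_size=10 ** 6, min_coherence=-1)
        assert out.sizes == {} and np.all(out.labels == -1)

    def test_identity_thresholds(self, planted_matrix):
        m, _, _ = planted_matrix
        S = similarity(preprocess(m))
        res = affinity_propagation(S)
        out = filter_coherent(res, S, min_size=0, min_coherence=-1.0)
        assert np.array_equal(out.labels, res.labels)

    def test_retained_count_matches_manual_count(self, planted_matrix):
        m, truth, _ = planted_matrix
        S = similarity(preprocess(m))
        res = affinity_propagation(S)
        out = filter_coherent(res, S, min_size=20, min_coherence=0.6)
        manual = sum(cnt for cid, cnt in res.sizes.items()
                     if cnt >= 20 and res.coherence[cid] >= 0.6)
        assert int(np.sum(out.labels >= 0)) == manual
        # the retained clusters are the planted ones
        assert len(out.sizes) == 3

    def test_planted_clusters_are_coherent(self, planted_matrix):
        # mean within-cluster correlation close to the variance-decomposition
        # prediction s2/(s2+sd2) = 0.8
        m, truth, info = planted_matrix
        S = similarity(preprocess(m))
        for cid in range(3):
            idx = np.where(truth == cid)[0]
            sub = S[np.ix_(idx, idx)]
            mean_off = sub[~np.eye(len(idx), dtype=bool)].mean()
            assert mean_off == pytest.approx(info["expected_within_corr"],
                                             rel=0.05)


def exhaustive_tail(k, M, n, N):
    """P(overlap >= k) by direct enumeration over the hypergeometric pmf."""
    total = 0.0
    for x in range(k, min(n, N) + 1):
        total += (math.comb(n, x) * math.comb(M - n, N - x)) / math.comb(M, N)
    return total


class TestOverlapEnrichment:
    def test_cluster_equal_universe_gives_one(self):
        u = {f"g{i}" for i in range(10)}
        assert overlap_enrichment(u, set(list(u)[:4]), u) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_small_universes(self):
        rng = np.random.default_rng(2)
        for M in range(5, 26, 5):
            universe = [f"g{i}" for i in range(M)]
            for _ in range(10):
                n = int(rng.integers(1, M + 1))
                N = int(rng.integers(1, M + 1))
                ref = list(rng.choice(universe, size=n, replace=False))
                clu = list(rng.choice(universe, size=N, replace=False))
                k = len(set(ref) & set(clu))
                got = overlap_enrichment(clu, ref, universe)
                want = exhaustive_tail(k, M, n, N)
                assert got == pytest.approx(want, rel=1e-10, abs=1e-300)

    def test_disjoint_sets_no_more_significant_than_overlap(self):
        universe = [f"g{i}" for i in range(20)]
        ref = universe[:10]
        p_disjoint = overlap_enrichment(universe[10:15], ref, universe)
        p_overlap = overlap_enrichment(universe[:5], ref, universe)
        assert p_disjoint >= p_overlap

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_enrichment([], [], [])

    def test_non_subset_rejected(self):
        with pytest.raises(ValueError):
            overlap_enrichment(["x"], [], ["y"])


class TestExpressionMatrixIO:
    def test_frame_round_trip(self, planted_matrix):
        m, _, _ = planted_matrix
        again = ExpressionMatrix.from_frame(m.to_frame())
        assert again.genes == m.genes
        assert again.conditions == m.conditions
        assert np.allclose(again.values, m.values)
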