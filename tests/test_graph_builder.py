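import math

import numpy as np
import pytest

from gatfp.graph_builder import (CorpusError, CorpusStats, EncodingError,
                                 NodeFeatureSpec, accumulate_corpus_stats,
                                 build_graph, build_vocabulary, compute_pmi,
                                 compute_tfidf, encode_node_features)
from gatfp.msio import FragmentNode

from conftest import random_tree


def brute_force_stats(trees):
    """Independent enumeration of corpus counts by exhaustive listing."""
    edges = []
    for t in trees:
        key = {n.node_id: n.formula_str for n in t.nodes}
        for p, c in t.edges:
            edges.append(tuple(sorted((key[p], key[c]))))
    formulas = sorted({f for t in trees for n in t.nodes for f in [n.formula_str]})
    w = len(edges)
    marg = {f: sum(1 for e in edges for x in e if x == f) for f in formulas}
    co = {}
    for e in set(edges):
        co[e] = edges.count(e)
    df = {f: sum(1 for t in trees if any(n.formula_str == f for n in t.nodes))
          for f in formulas}
    return w, marg, co, df


class TestVocabulary:
    def test_distinct_formulas_indexed(self, toy_corpus):
        vocab = build_vocabulary(toy_corpus.trees)
        assert vocab.size == 4
        assert sorted(vocab.key_of.values()) == [0, 1, 2, 3]

    def test_order_invariance(self, toy_corpus):
        a = build_vocabulary(toy_corpus.trees)
        b = build_vocabulary(toy_corpus.trees[::-1])
        assert a.key_of == b.key_of

    def test_empty_corpus_rejected(self):
        with pytest.raises(CorpusError):
            build_vocabulary([])

    def test_unk_reserved_last(self, toy_corpus):
        vocab = build_vocabulary(toy_corpus.trees, reserve_unk=True)
        assert vocab.size == 5
        assert vocab.index({"C": 9, "H": 9}) == 4


class TestCorpusStats:
    def test_single_edge_counts(self, rng):
        t = random_tree(rng, "s", 2)
        vocab = build_vocabulary([t])
        stats = accumulate_corpus_stats([t], vocab)
        assert stats.total_edges == 1
        assert stats.n_samples == 1
        assert all(v == 1 for v in stats.frag_edge_count.values())
        assert sum(stats.co_count.values()) == 1

    def test_additivity_over_corpus_copies(self, rng):
        t = random_tree(rng, "s", 4)
        vocab = build_vocabulary([t])
        one = accumulate_corpus_stats([t], vocab)
        two = accumulate_corpus_stats([t, t], vocab)
        assert two.total_edges == 2 * one.total_edges
        assert two.co_count == {k: 2 * v for k, v in one.co_count.items()}
        assert two.doc_freq == {k: 2 * v for k, v in one.doc_freq.items()}

    def test_matches_brute_force_enumeration(self, rng):
        """Counts agree with an exhaustive listing on random tiny corpora."""
        for trial in range(10):
            trees = [random_tree(rng, f"s{i}", int(rng.integers(1, 6)))
                     for i in range(int(rng.integers(2, 8)))]
            vocab = build_vocabulary(trees)
            stats = accumulate_corpus_stats(trees, vocab)
            w, marg, co, df = brute_force_stats(trees)
            assert stats.total_edges == w
            inv = {v: k for k, v in vocab.key_of.items()}
            for i, c in stats.frag_edge_count.items():
                assert c == marg[inv[i]]
            for (i, j), c in stats.co_count.items():
                assert c == co[tuple(sorted((inv[i], inv[j])))]
            for j, c in stats.doc_freq.items():
                assert c == df[inv[j]]

    def test_co_count_bounded_by_marginals(self, rng):
        trees = [random_tree(rng, f"s{i}", 5) for i in range(6)]
        vocab = build_vocabulary(trees)
        stats = accumulate_corpus_stats(trees, vocab)
        for (i, j), cij in stats.co_count.items():
            assert cij <= min(stats.frag_edge_count[i], stats.frag_edge_count[j])


def make_stats(w, ci, cj, cij, s=1, fj=None):
    return CorpusStats(co_count={(0, 1): cij}, frag_edge_count={0: ci, 1: cj},
                       total_edges=w, doc_freq=fj or {0: 1, 1: 1}, n_samples=s)


class TestPMI:
    def test_independent_pair_is_zero(self):
        assert compute_pmi(0, 1, make_stats(4, 2, 2, 1)) == pytest.approx(0.0)

    def test_derived_values(self):
        # direct arithmetic on the definition: ln(p(i,j)/(p(i)p(j)))
        assert compute_pmi(0, 1, make_stats(4, 2, 2, 2)) == pytest.approx(
            math.log(2), abs=1e-12)
        assert compute_pmi(0, 1, make_stats(100, 1, 1, 1)) == pytest.approx(
            math.log(100), abs=1e-12)

    def test_symmetry(self):
        st = make_stats(10, 4, 3, 2)
        assert compute_pmi(0, 1, st) == compute_pmi(1, 0, st)

    def test_zero_count_raises(self):
        with pytest.raises(CorpusError):
            compute_pmi(0, 1, make_stats(4, 2, 2, 0))

    def test_oracle_equivalence_random_corpora(self, rng):
        """PMI agrees with direct evaluation on exhaustively-counted corpora."""
        for trial in range(5):
            trees = [random_tree(rng, f"s{i}", int(rng.integers(2, 6)))
                     for i in range(int(rng.integers(2, 10)))]
            vocab = build_vocabulary(trees)
            stats = accumulate_corpus_stats(trees, vocab)
            w, marg, co, df = brute_force_stats(trees)
            inv = {v: k for k, v in vocab.key_of.items()}
            for (i, j) in stats.co_count:
                expect = math.log((co[tuple(sorted((inv[i], inv[j])))] / w)
                                  / ((marg[inv[i]] / w) * (marg[inv[j]] / w)))
                assert compute_pmi(i, j, stats) == pytest.approx(expect, abs=1e-12)


class TestTFIDF:
    def test_everywhere_fragment_scores_zero(self, toy_corpus):
        """A fragment present in every sample has IDF ln(1) = 0."""
        vocab = build_vocabulary(toy_corpus.trees)
        stats = accumulate_corpus_stats(toy_corpus.trees, vocab)
        j = vocab.index("CH2O")  # in all three toy trees
        for t in toy_corpus.trees:
            assert compute_tfidf(t, j, stats, vocab) == 0.0

    def test_absent_fragment_scores_zero(self, toy_corpus):
        vocab = build_vocabulary(toy_corpus.trees)
        stats = accumulate_corpus_stats(toy_corpus.trees, vocab)
        j = vocab.index("H2O")  # only in t2
        t3 = toy_corpus.trees[2]
        assert compute_tfidf(t3, j, stats, vocab) == 0.0

    def test_derived_value(self, rng):
        # S=10, F_j=1, TF=0.5 -> 0.5 * ln 10
        t = random_tree(rng, "s0", 2)
        vocab = build_vocabulary([t])
        j = vocab.index(t.nodes[1].formula_str)
        tf = t.nodes[1].rel_intensity
        stats = CorpusStats(co_count={}, frag_edge_count={}, total_edges=0,
                            doc_freq={j: 1}, n_samples=10)
        assert compute_tfidf(t, j, stats, vocab) == pytest.approx(
            tf * math.log(10), abs=1e-12)


class TestNodeEncoding:
    def test_block_layout(self):
        spec = NodeFeatureSpec(element_alphabet=("C", "H", "O"), max_count=3)
        node = FragmentNode(node_id=0, formula={"H": 2, "O": 1}, mz=18.011,
                            rel_intensity=0.5)
        v = encode_node_features(node, spec)
        assert v.shape == (spec.width,) == (14,)
        np.testing.assert_array_equal(v[0:4], [1, 0, 0, 0])    # C count 0
        np.testing.assert_array_equal(v[4:8], [0, 0, 1, 0])    # H count 2
        np.testing.assert_array_equal(v[8:12], [0, 1, 0, 0])   # O count 1
        assert v[12] == pytest.approx(18.011 / 1000)
        assert v[13] == 0.5

    def test_count_clamped_at_cap(self):
        spec = NodeFeatureSpec(element_alphabet=("C", "H"), max_count=3,
                               include_mz=False, include_intensity=False)
        node = FragmentNode(node_id=0, formula={"C": 7, "H": 1}, mz=85.0,
                            rel_intensity=1.0)
        v = encode_node_features(node, spec)
        np.testing.assert_array_equal(v[0:4], [0, 0, 0, 1])  # capped at 3

    def test_ffv_keeps_only_intensity(self):
        spec = NodeFeatureSpec.ffv()
        node = FragmentNode(node_id=0, formula={"C": 1, "H": 2, "O": 1},
                            mz=30.0, rel_intensity=0.7)
        v = encode_node_features(node, spec)
        assert v.shape == (1,) and v[0] == 0.7

    def test_alien_element_rejected(self):
        spec = NodeFeatureSpec(element_alphabet=("C", "H"))
        node = FragmentNode(node_id=0, formula={"N": 1, "H": 3}, mz=17.0,
                            rel_intensity=1.0)
        with pytest.raises(EncodingError):
            encode_node_features(node, spec)

    @pytest.mark.parametrize("kw", [
        {}, {"include_mz": False}, {"include_elements": False},
        {"max_count": 4, "element_alphabet": ("C", "H", "N", "O")},
    ])
    def test_width_formula(self, kw, rng):
        spec = NodeFeatureSpec(**kw)
        t = random_tree(rng, "s", 3)
        for n in t.nodes:
            assert encode_node_features(n, spec).shape == (spec.width,)


class TestBuildGraph:
    def test_single_node_graph(self, rng):
        t = random_tree(rng, "s", 1)
        vocab = build_vocabulary([t])
        stats = accumulate_corpus_stats([t], vocab)
        spec = NodeFeatureSpec(element_alphabet=("C", "H", "O"))
        g = build_graph(t, vocab, stats, spec, np.array([0, 1]))
        assert g.node_features.shape == (1, spec.width)
        assert g.edge_index.shape == (0, 2)

    def test_two_node_self_corpus_edge_is_zero_zero(self, rng):
        """In a 1-tree corpus, the lone edge has PMI 0 and child TF-IDF 0."""
        t = random_tree(rng, "s", 2)
        vocab = build_vocabulary([t])
        stats = accumulate_corpus_stats([t], vocab)
        spec = NodeFeatureSpec(element_alphabet=("C", "H", "O"))
        g = build_graph(t, vocab, stats, spec, np.array([1]),
                        add_reverse_edges=False)
        np.testing.assert_allclose(g.edge_features, [[0.0, 0.0]], atol=1e-12)

    def test_ffe_mode_all_ones(self, toy_corpus):
        vocab = build_vocabulary(toy_corpus.trees)
        stats = accumulate_corpus_stats(toy_corpus.trees, vocab)
        spec = NodeFeatureSpec(element_alphabet=("C", "H", "O"))
        g = build_graph(toy_corpus.trees[0], vocab, stats, spec,
                        np.array([1, 0]), edge_mode="ones")
        np.testing.assert_array_equal(g.edge_features,
                                      np.ones_like(g.edge_features))

    def test_reverse_edges_double_count(self, toy_corpus):
        vocab = build_vocabulary(toy_corpus.trees)
        stats = accumulate_corpus_stats(toy_corpus.trees, vocab)
        spec = NodeFeatureSpec(element_alphabet=("C", "H", "O"))
        t = toy_corpus.trees[0]
        fwd = build_graph(t, vocab, stats, spec, np.array([1]),
                          add_reverse_edges=False)
        both = build_graph(t, vocab, stats, spec, np.array([1]))
        assert both.edge_index.shape[0] == 2 * fwd.edge_index.shape[0]
        np.testing.assert_array_equal(both.edge_index[: len(t.edges)][:, ::-1],
                                      both.edge_index[len(t.edges):])

    def test_unseen_pair_raises_or_zeros(self):
        from gatfp.msio import FragmentationTree

        def node(nid, comp, mz):
            return FragmentNode(node_id=nid, formula=comp, mz=mz,
                                rel_intensity=1.0)

        # train chain C3H6 -> C2H4 -> CH2: pair (C3H6, CH2) never on an edge
        t_train = FragmentationTree(
            "a", [node(0, {"C": 3, "H": 6}, 43.0), node(1, {"C": 2, "H": 4}, 29.0),
                  node(2, {"C": 1, "H": 2}, 15.0)],
            [(0, 1), (1, 2)], 43.0, {"C": 3, "H": 6})
        t_test = FragmentationTree(
            "b", [node(0, {"C": 3, "H": 6}, 43.0), node(1, {"C": 1, "H": 2}, 15.0)],
            [(0, 1)], 43.0, {"C": 3, "H": 6})
        vocab = build_vocabulary([t_train], reserve_unk=True)
        stats = accumulate_corpus_stats([t_train], vocab)
        spec = NodeFeatureSpec(element_alphabet=("C", "H"))
        # (C3H6, CH2) never co-occur on a training edge
        with pytest.raises(CorpusError):
            build_graph(t_test, vocab, stats, spec, np.array([1]))
        g = build_graph(t_test, vocab, stats, spec, np.array([1]),
                        missing_pair="zero", add_reverse_edges=False)
        assert g.edge_features[0, 0] == 0.0
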