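import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from semrank.corpus_stats import compute_statistics
from semrank.ranking import (
    BM25Index,
    RunEntry,
    SemRankConfig,
    bm25_score,
    bm25_search,
    dmm_score,
    rerank_run,
    rsv_cosine,
    semrank_fuse,
)
from semrank.semantics import fixture_similarity_matrix
from semrank.vocabulary import MDFAnnotation, annotate


class TestBM25:
    def test_no_query_term_in_document(self):
        assert bm25_score(["x"], ["y", "z"], 10, {"x": 3}, 2.0) == 0.0

    def test_single_document_hand_value(self):
        # N=1, term present once, dl == avgdl: idf = ln(4/3), tf part = 1.
        got = bm25_score(["term"], ["term", "other"], 1, {"term": 1, "other": 1}, 2.0)
        assert got == pytest.approx(math.log(4.0 / 3.0), abs=1e-12)

    def test_monotone_in_tf(self):
        df = {"t": 5}
        scores = [
            bm25_score(["t"], ["t"] * tf + ["x"] * (10 - tf), 20, df, 10.0)
            for tf in range(1, 8)
        ]
        assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_search_top_k_and_ties(self):
        corpus = {"docB": "apple pie", "docA": "apple pie", "docC": "banana"}
        index = BM25Index(corpus)
        hits = index.search("q1", "apple", k=10)
        assert [e.doc_id for e in hits] == ["docA", "docB"]  # tie -> id order
        assert [e.rank for e in hits] == [1, 2]
        assert index.search("q1", "apple", k=1)[0].doc_id == "docA"
        assert len(index.search("q1", "apple pie banana", k=99)) == 3

    def test_search_unknown_query_id(self):
        index = BM25Index({"d": "text"})
        with pytest.raises(KeyError):
            bm25_search(index, {"q1": "text"}, "missing", 5)


class TestCosine:
    def test_identical_nonzero_vectors(self):
        v = np.array([0.3, 0.1, 0.0, 0.0, 0.0, 2.0])
        assert rsv_cosine(v, v) == pytest.approx(1.0)

    def test_orthogonal_and_zero(self):
        assert rsv_cosine(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0
        assert rsv_cosine(np.zeros(3), np.ones(3)) == 0.0

    def test_hand_value(self):
        q = np.array([1.0, 1.0, 0.0, 0.0, 0.0, 0.0])
        d = np.array([1.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        assert rsv_cosine(q, d) == pytest.approx(1.0 / math.sqrt(2.0), abs=1e-12)


class TestDMMScore:
    def test_bounds_and_zero_propagation(self, default_vocab):
        ssm = fixture_similarity_matrix(default_vocab, seed=4)
        docs = [annotate(t, default_vocab) for t in ("mri cancer", "ct skin", "gel")]
        stats = compute_statistics(docs)
        same = dmm_score(docs[0], docs[0], ssm, stats, doc_rank=1)
        assert 0.0 <= same <= 1.0
        empty = MDFAnnotation(())
        assert dmm_score(empty, docs[0], ssm, stats, doc_rank=1) == 0.0

    def test_deterministic_to_1e12(self, default_vocab):
        ssm = fixture_similarity_matrix(default_vocab, seed=4)
        docs = [annotate(t, default_vocab) for t in ("mri cancer", "ct skin biopsy")]
        stats = compute_statistics(docs)
        a = dmm_score(docs[0], docs[1], ssm, stats, doc_rank=2)
        b = dmm_score(docs[0], docs[1], ssm, stats, doc_rank=2)
        assert abs(a - b) <= 1e-12


def _baseline(scores):
    return [
        RunEntry("q", doc, r + 1, s, "BM25")
        for r, (doc, s) in enumerate(sorted(scores.items(), key=lambda kv: (-kv[1], kv[0])))
    ]


class TestFusion:
    def test_alpha_one_keeps_baseline_order(self):
        base = _baseline({"a": 3.0, "b": 2.0, "c": 1.0})
        fused = semrank_fuse(base, {"a": 0.0, "b": 5.0, "c": 9.0}, alpha=1.0)
        assert [e.doc_id for e in fused] == ["a", "b", "c"]

    def test_alpha_zero_orders_by_dmm(self):
        base = _baseline({"a": 3.0, "b": 2.0, "c": 1.0})
        fused = semrank_fuse(base, {"a": 0.1, "b": 5.0, "c": 9.0}, alpha=0.0)
        assert [e.doc_id for e in fused] == ["c", "b", "a"]

    def test_hand_arithmetic(self):
        base = _baseline({"a": 10.0, "b": 5.0})
        fused = semrank_fuse(base, {"a": 2.0, "b": 1.0}, alpha=0.3)
        by_id = {e.doc_id: e.score for e in fused}
        assert by_id["a"] == pytest.approx(1.0, abs=1e-12)
        # normalized init 0.5, normalized dmm 0.5 -> 0.3*0.5 + 0.7*0.5
        assert by_id["b"] == pytest.approx(0.5, abs=1e-12)
        fused2 = semrank_fuse(base, {"a": 2.0, "b": 1.0}, alpha=0.3)
        assert fused == fused2

    def test_point_value_065(self):
        base = _baseline({"a": 1.0, "b": 1.0})
        # normalized init 1.0 for both; dmm 1.0 vs 0.5
        fused = semrank_fuse(base, {"a": 1.0, "b": 0.5}, alpha=0.3)
        by_id = {e.doc_id: e.score for e in fused}
        assert by_id["b"] == pytest.approx(0.65, abs=1e-12)

    def test_extra_dmm_docs_ignored(self, caplog):
        base = _baseline({"a": 1.0})
        fused = semrank_fuse(base, {"a": 1.0, "ghost": 9.0}, alpha=0.5)
        assert [e.doc_id for e in fused] == ["a"]

    def test_nonpositive_maxima_normalize_to_zero(self):
        base = _baseline({"a": 0.0, "b": 0.0})
        fused = semrank_fuse(base, {"a": 0.0, "b": 0.0}, alpha=0.3)
        assert all(e.score == 0.0 for e in fused)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        rows=st.lists(
            st.tuples(
                st.floats(0, 100, allow_nan=False),
                st.floats(0, 1, allow_nan=False),
            ),
            min_size=1,
            max_size=20,
        ),
        alpha=st.floats(0, 1, allow_nan=False),
    )
    def test_matches_brute_force_oracle(self, rows, alpha):
        scores = {f"d{i:02d}": s for i, (s, _) in enumerate(rows)}
        dmm = {f"d{i:02d}": v for i, (_, v) in enumerate(rows)}
        base = _baseline(scores)
        fused = semrank_fuse(base, dmm, alpha)
        want = oracles.o_fuse([(e.doc_id, e.score) for e in base], dmm, alpha)
        assert [e.doc_id for e in fused] == want
        assert all(0.0 <= e.score <= 1.0 + 1e-12 for e in fused)
        if any(s > 0 for s in scores.values()):
            assert max(e.score for e in fused) >= alpha  # some doc attains init 1


@pytest.fixture(scope="module")
def small_world(default_vocab):
    from semrank.synthetic import SynthConfig, generate_collection

    ssm = fixture_similarity_matrix(default_vocab, seed=77)
    coll = generate_collection(
        SynthConfig(n_docs=60, n_queries=4, seed=77), default_vocab, ssm
    )
    return default_vocab, ssm, coll


class TestRerankRun:
    def test_alpha_one_equals_baseline_run(self, small_world):
        vocab, ssm, coll = small_world
        cfg = SemRankConfig(alpha=1.0, rerank_depth=50)
        entries = rerank_run(coll.documents, coll.queries, vocab, ssm, cfg)
        index = BM25Index(coll.documents)
        for qid, qtext in coll.queries.items():
            base = index.search(qid, qtext, 50)
            got = [e.doc_id for e in entries if e.query_id == qid]
            assert got == [e.doc_id for e in base]

    def test_output_is_permutation_of_candidates(self, small_world):
        vocab, ssm, coll = small_world
        cfg = SemRankConfig(alpha=0.3, rerank_depth=50)
        entries = rerank_run(coll.documents, coll.queries, vocab, ssm, cfg)
        index = BM25Index(coll.documents)
        for qid, qtext in coll.queries.items():
            base = {e.doc_id for e in index.search(qid, qtext, 50)}
            got = [e.doc_id for e in entries if e.query_id == qid]
            assert set(got) == base and len(got) == len(base)

    def test_deterministic(self, small_world):
        vocab, ssm, coll = small_world
        cfg = SemRankConfig(alpha=0.3, rerank_depth=30)
        a = rerank_run(coll.documents, coll.queries, vocab, ssm, cfg)
        b = rerank_run(coll.documents, coll.queries, vocab, ssm, cfg)
        assert a == b
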