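import math

import numpy as np
import pytest

import oracles
from semrank.corpus_stats import compute_statistics
from semrank.filters import (
    FilterContext,
    co_df,
    co_qf,
    compute_filter_scores,
    fd_df,
    fd_qf,
    l_df,
    l_qf,
    p_df,
    p_qf,
    pmi_df,
    pmi_qf,
    r_df,
    r_qf,
)
from semrank.vocabulary import MDFAnnotation


def ctx(ref, q, doc, rank=None):
    return FilterContext(
        query=MDFAnnotation(tuple(q)),
        document=doc,
        stats=ref.stats,
        doc_rank=rank,
    )


EMPTY = MDFAnnotation(())


class TestQueryFilters:
    def test_co_qf(self, ref):
        assert co_qf(ctx(ref, [ref.a], ref.d2)) == pytest.approx(0.5)
        assert co_qf(ctx(ref, [ref.d], ref.d1)) == pytest.approx(0.25)
        assert co_qf(ctx(ref, [ref.a], EMPTY)) == 0.0

    def test_l_qf(self, ref):
        assert l_qf(ctx(ref, [ref.a], ref.d1)) == pytest.approx(0.5)
        assert l_qf(ctx(ref, [ref.a, ref.b], ref.d1)) == pytest.approx(1.0)
        assert l_qf(ctx(ref, [ref.a, ref.b], ref.d3)) == 0.0  # b missing

    def test_r_qf(self, ref):
        assert r_qf(ctx(ref, [ref.a], ref.d1, rank=1)) == 1.0
        assert r_qf(ctx(ref, [ref.a], ref.d1, rank=4)) == 0.25
        assert r_qf(ctx(ref, [ref.a], ref.d1, rank=None)) == 0.0

    def test_p_qf(self, ref):
        assert p_qf(ctx(ref, [ref.a, ref.d], ref.d3)) == pytest.approx(0.5)
        assert p_qf(ctx(ref, [ref.a], ref.d3)) == 1.0  # single occurrence
        assert p_qf(ctx(ref, [ref.b], ref.d3)) == 0.0  # absent

    def test_pmi_qf(self, ref):
        assert pmi_qf(ctx(ref, [ref.a], ref.d2)) == pytest.approx(
            math.log(0.75), abs=1e-4
        )
        assert pmi_qf(ctx(ref, [ref.d], ref.d1)) == pytest.approx(
            math.log(1.5), abs=1e-4
        )
        assert pmi_qf(ctx(ref, [ref.b], MDFAnnotation((ref.d,)))) == 0.0

    def test_fd_qf_variants(self, ref):
        assert fd_qf(ctx(ref, [ref.a], ref.d1)) == 1.0  # subset
        assert fd_qf(ctx(ref, [ref.a, ref.b, ref.d], ref.d1)) == pytest.approx(0.5)
        assert fd_qf(ctx(ref, [ref.b, ref.c, ref.d], MDFAnnotation((ref.a,)))) == 0.25
        assert fd_qf(
            ctx(ref, [ref.a, ref.b, ref.d], ref.d1), variant="intersection"
        ) == pytest.approx(1.0 / 3.0)


class TestDocumentFilters:
    def test_co_df(self, ref):
        assert co_df(ctx(ref, [ref.a, ref.b], ref.d3)) == 1
        assert co_df(ctx(ref, [ref.b], ref.d3)) == 0
        assert co_df(ctx(ref, [ref.a, ref.c, ref.d], ref.d3)) == 3

    def test_l_df(self, ref):
        assert l_df(ctx(ref, [ref.a, ref.d], ref.d3)) == pytest.approx(2.0 / 3.0)
        assert l_df(ctx(ref, [ref.a], EMPTY)) == 0.0
        assert l_df(ctx(ref, [ref.a, ref.b, ref.c], ref.d1)) == 1.0

    def test_r_df_organization_factor(self, ref):
        assert r_df(ctx(ref, [ref.a, ref.c], ref.d3)) == pytest.approx(2.0)
        assert r_df(ctx(ref, [ref.c, ref.a], ref.d3)) == pytest.approx(1.0)
        assert r_df(ctx(ref, [ref.b], ref.d3)) == 0.0

    def test_p_df(self, ref):
        assert p_df(ctx(ref, [ref.a, ref.d], ref.d3)) == pytest.approx(0.5)
        assert p_df(ctx(ref, [ref.a], ref.d3)) == 1.0
        assert p_df(ctx(ref, [ref.b], ref.d3)) == 0.0

    def test_pmi_df(self, ref):
        expect = (math.log(0.75) + math.log(1.5) + math.log(1.5)) / 3.0
        assert pmi_df(ctx(ref, [], ref.d3)) == pytest.approx(expect, abs=1e-4)
        assert pmi_df(ctx(ref, [], MDFAnnotation((ref.a,)))) == 0.0
        assert pmi_df(ctx(ref, [], ref.d1)) == pytest.approx(math.log(0.5), abs=1e-4)

    def test_fd_df(self, ref):
        assert fd_df(ctx(ref, [ref.a, ref.b, ref.c, ref.d], ref.d3)) == 1.0
        assert fd_df(ctx(ref, [ref.a], ref.d3)) == pytest.approx(1.0 / 3.0)
        assert fd_df(ctx(ref, [ref.c], ref.d1)) == pytest.approx(1.0 / 3.0)


class TestComputeFilterScores:
    def test_empty_query_and_document(self, ref):
        fs = compute_filter_scores(
            FilterContext(query=EMPTY, document=EMPTY, stats=ref.stats)
        )
        assert fs.fd_qf == 1.0 and fs.fd_df == 1.0
        for name in ("co_qf", "l_qf", "r_qf", "p_qf", "pmi_qf",
                     "co_df", "l_df", "r_df", "p_df", "pmi_df"):
            assert getattr(fs, name) == 0.0

    def test_reference_pair_all_twelve(self, ref):
        fs = compute_filter_scores(ctx(ref, [ref.a], ref.d1, rank=1))
        assert fs.co_qf == pytest.approx(0.75)
        assert fs.l_qf == pytest.approx(0.5)
        assert fs.r_qf == 1.0
        assert fs.p_qf == 1.0
        assert fs.fd_qf == 1.0
        assert fs.co_df == 1.0
        assert fs.l_df == pytest.approx(0.5)
        assert fs.r_df == 1.0
        assert fs.p_df == 1.0
        assert fs.fd_df == pytest.approx(0.5)

    def test_deterministic(self, ref):
        c = ctx(ref, [ref.a, ref.d], ref.d3, rank=2)
        assert compute_filter_scores(c) == compute_filter_scores(c)


def _random_context(rng):
    n = int(rng.integers(2, 9))
    corpus = [
        list(rng.integers(0, n, size=rng.integers(0, 7))) for _ in range(rng.integers(1, 7))
    ]
    q = list(rng.integers(0, n, size=rng.integers(0, 5)))
    doc = corpus[int(rng.integers(0, len(corpus)))]
    rank = None if rng.random() < 0.3 else int(rng.integers(1, 30))
    return corpus, q, doc, rank


def _package_scores(corpus, q, doc, rank):
    stats = compute_statistics([MDFAnnotation(tuple(d)) for d in corpus])
    return compute_filter_scores(
        FilterContext(
            query=MDFAnnotation(tuple(q)),
            document=MDFAnnotation(tuple(doc)),
            stats=stats,
            doc_rank=rank,
        )
    )


class TestBruteForceOracleSuite:
    def test_all_filters_match_oracles_on_random_contexts(self):
        """Primary oracle suite: 1,000 random tiny contexts."""
        rng = np.random.default_rng(20240606)
        for _ in range(1000):
            corpus, q, doc, rank = _random_context(rng)
            fs = _package_scores(corpus, q, doc, rank)
            assert fs.r_qf == oracles.o_r_qf(rank)
            for name, oracle, exact in oracles.QUERY_ORACLES + oracles.DOCUMENT_ORACLES:
                got = getattr(fs, name)
                want = oracle(corpus, q, doc)
                if exact:
                    assert got == want, (name, corpus, q, doc)
                else:
                    assert got == pytest.approx(want, abs=1e-12), (name, corpus, q, doc)

    def test_bounded_filters_stay_in_unit_interval(self):
        rng = np.random.default_rng(7)
        bounded = ("l_qf", "r_qf", "p_qf", "fd_qf", "l_df", "p_df", "fd_df")
        for _ in range(300):
            corpus, q, doc, rank = _random_context(rng)
            fs = _package_scores(corpus, q, doc, rank)
            for name in bounded:
                assert 0.0 <= getattr(fs, name) <= 1.0
            assert fs.co_df == int(fs.co_df) >= 0

    def test_monotonicity_under_document_edits(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            corpus, q, doc, rank = _random_context(rng)
            if not q:
                continue
            fs = _package_scores(corpus, q, doc, rank)
            # adding a query MDF to D never decreases the overlap count
            grown = doc + [q[0]]
            fs_grown = _package_scores(corpus, q, grown, rank)
            assert fs_grown.co_df >= fs.co_df
            # adding a non-query MDF never increases FDDF
            alien = max(list(q) + list(doc), default=0) + 1
            fs_alien = _package_scores(corpus, q, doc + [alien], rank)
            assert fs_alien.fd_df <= fs.fd_df
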