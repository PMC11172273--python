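"""BM25 first-pass retrieval, deep matching score, and SemRank fusion.

The pipeline is a re-ranker: BM25 over the raw caption text produces a
candidate list per query; each candidate is re-scored by the deep
matching model (DMM) — filters, forward pass, cosine between the query
and document representations — and the final SemRank score is the convex
combination of the max-normalized baseline and DMM scores,

    SemRank = alpha * init/max(init) + (1 - alpha) * dmm/max(dmm),

with the maxima taken over the query's candidate list.  Sorting by the
fused score re-ranks the candidates; alpha = 1 recovers the baseline
ordering and alpha = 0 the DMM ordering.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from math import log
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus_stats import CorpusStatistics, compute_statistics
from .filters import FilterContext, compute_filter_scores
from .network import NetworkConfig, Representation, represent
from .semantics import SemanticSimilarityMatrix, build_feature_matrix
from .vocabulary import MDFAnnotation, MDFVocabulary, annotate, to_binary_vector

__all__ = [
    "RunEntry",
    "SemRankConfig",
    "tokenize",
    "bm25_score",
    "BM25Index",
    "bm25_search",
    "rsv_cosine",
    "dmm_score",
    "semrank_fuse",
    "rerank_run",
]

logger = logging.getLogger(__name__)

_WORD_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercase, split on whitespace/punctuation."""
    return _WORD_RE.findall(text.lower())


@dataclass(frozen=True)
class RunEntry:
    """One scored document in a per-query ranked list (TREC run row)."""

    query_id: str
    doc_id: str
    rank: int
    score: float
    tag: str = "run"


@dataclass(frozen=True)
class SemRankConfig:
    """Fusion and baseline parameters."""

    alpha: float = 0.3
    rerank_depth: int = 1000
    bm25_k1: float = 1.2
    bm25_b: float = 0.75
    fdqf_variant: str = "missing"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.rerank_depth < 1:
            raise ValueError("rerank_depth must be >= 1")


def bm25_score(
    query_tokens: Sequence[str],
    doc_tokens: Sequence[str],
    n_docs: int,
    df: Mapping[str, int],
    avgdl: float,
    k1: float = 1.2,
    b: float = 0.75,
) -> float:
    """Okapi BM25 with non-negative idf = ln(1 + (N - df + 0.5)/(df + 0.5)).

    Summed over the distinct query terms present in the document; tf
    saturation uses the usual (k1 + 1) numerator with length
    normalization dl/avgdl.
    """
    tf = Counter(doc_tokens)
    dl = len(doc_tokens)
    norm = k1 * (1.0 - b + b * (dl / avgdl if avgdl > 0 else 0.0))
    score = 0.0
    for term in set(query_tokens):
        t = tf.get(term, 0)
        if t == 0:
            continue
        d = df.get(term, 0)
        idf = log(1.0 + (n_docs - d + 0.5) / (d + 0.5))
        score += idf * t * (k1 + 1.0) / (t + norm)
    return score


class BM25Index:
    """Inverted index over a corpus of raw texts for BM25 retrieval."""

    def __init__(self, corpus: Mapping[str, str], k1: float = 1.2, b: float = 0.75):
        self.k1 = k1
        self.b = b
        self.doc_ids = list(corpus)
        self.doc_len: dict[str, int] = {}
        self.postings: dict[str, dict[str, int]] = {}
        for doc_id, text in corpus.items():
            toks = tokenize(text)
            self.doc_len[doc_id] = len(toks)
            for term, t in Counter(toks).items():
                self.postings.setdefault(term, {})[doc_id] = t
        self.n_docs = len(self.doc_ids)
        total = sum(self.doc_len.values())
        self.avgdl = total / self.n_docs if self.n_docs else 0.0

    def df(self, term: str) -> int:
        return len(self.postings.get(term, ()))

    def score(self, query_text: str, doc_id: str) -> float:
        """BM25 score of one document for a query (0 if no term matches)."""
        qtokens = set(tokenize(query_text))
        score = 0.0
        for term in qtokens:
            posting = self.postings.get(term)
            if not posting or doc_id not in posting:
                continue
            t = posting[doc_id]
            d = len(posting)
            idf = log(1.0 + (self.n_docs - d + 0.5) / (d + 0.5))
            dl = self.doc_len[doc_id]
            norm = self.k1 * (1.0 - self.b + self.b * (dl / self.avgdl if self.avgdl else 0.0))
            score += idf * t * (self.k1 + 1.0) / (t + norm)
        return score

    def search(self, query_id: str, query_text: str, k: int) -> list[RunEntry]:
        """Top-k documents with a positive score; ties broken by doc_id."""
        qtokens = set(tokenize(query_text))
        acc: dict[str, float] = {}
        for term in qtokens:
            posting = self.postings.get(term)
            if not posting:
                continue
            d = len(posting)
            idf = log(1.0 + (self.n_docs - d + 0.5) / (d + 0.5))
            for doc_id, t in posting.items():
                dl = self.doc_len[doc_id]
                norm = self.k1 * (
                    1.0 - self.b + self.b * (dl / self.avgdl if self.avgdl else 0.0)
                )
                acc[doc_id] = acc.get(doc_id, 0.0) + idf * t * (self.k1 + 1.0) / (t + norm)
        ordered = sorted(acc.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
        return [
            RunEntry(query_id=query_id, doc_id=doc_id, rank=r + 1, score=s, tag="BM25")
            for r, (doc_id, s) in enumerate(ordered)
        ]


def bm25_search(
    index: BM25Index, queries: Mapping[str, str], query_id: str, k: int
) -> list[RunEntry]:
    """Search one query of a query set by id."""
    if query_id not in queries:
        raise KeyError(f"unknown query id {query_id!r}")
    return index.search(query_id, queries[query_id], k)


def rsv_cosine(q: Representation | np.ndarray, d: Representation | np.ndarray) -> float:
    """Cosine similarity between representations; 0 if either norm is 0."""
    qv = q.vector if isinstance(q, Representation) else np.asarray(q, float)
    dv = d.vector if isinstance(d, Representation) else np.asarray(d, float)
    if qv.shape != dv.shape:
        raise ValueError(f"representation shapes differ: {qv.shape} vs {dv.shape}")
    nq, nd = np.linalg.norm(qv), np.linalg.norm(dv)
    if nq == 0.0 or nd == 0.0:
        return 0.0
    return float(qv @ dv / (nq * nd))


def dmm_score(
    query_ann: MDFAnnotation,
    doc_ann: MDFAnnotation,
    ssm: SemanticSimilarityMatrix,
    stats: CorpusStatistics,
    doc_rank: int | None = None,
    net_cfg: NetworkConfig | None = None,
    fdqf_variant: str = "missing",
) -> float:
    """Deep matching score of one (query, document) pair.

    Builds both feature matrices, evaluates the twelve filters, runs the
    forward pass for each side and returns the cosine between the two
    representations.  Deterministic.
    """
    if net_cfg is None:
        net_cfg = NetworkConfig()
    Vq = to_binary_vector(query_ann, ssm.n)
    Vd = to_binary_vector(doc_ann, ssm.n)
    scores = compute_filter_scores(
        FilterContext(query=query_ann, document=doc_ann, stats=stats, doc_rank=doc_rank),
        fdqf_variant=fdqf_variant,
    )
    q_rep = represent(
        build_feature_matrix(Vq, ssm, owner="query"),
        scores.query_vector(),
        Vq,
        net_cfg,
        owner="query",
    )
    d_rep = represent(
        build_feature_matrix(Vd, ssm, owner="document"),
        scores.document_vector(),
        Vd,
        net_cfg,
        owner="document",
    )
    return rsv_cosine(q_rep, d_rep)


def semrank_fuse(
    baseline: Sequence[RunEntry],
    dmm_scores: Mapping[str, float],
    alpha: float,
    tag: str = "SemRank",
) -> list[RunEntry]:
    """Late fusion of a baseline candidate list with DMM scores.

    Each component is normalized by its maximum over the candidate list
    (a non-positive maximum normalizes to 0), combined as
    alpha * init + (1 - alpha) * dmm, and the candidates are re-sorted by
    the fused score with ties broken by higher baseline score then doc_id.
    DMM scores for documents outside the candidate list are ignored with a
    warning — fusion re-ranks the baseline list, it cannot add to it.
    """
    if not baseline:
        return []
    candidates = {e.doc_id for e in baseline}
    extra = set(dmm_scores) - candidates
    if extra:
        logger.warning(
            "ignoring DMM scores for %d document(s) outside the candidate list",
            len(extra),
        )
    max_init = max(e.score for e in baseline)
    max_dmm = max((dmm_scores.get(e.doc_id, 0.0) for e in baseline), default=0.0)
    fused: list[tuple[float, RunEntry]] = []
    for e in baseline:
        init_n = e.score / max_init if max_init > 0 else 0.0
        dmm_n = dmm_scores.get(e.doc_id, 0.0) / max_dmm if max_dmm > 0 else 0.0
        fused.append((alpha * init_n + (1.0 - alpha) * dmm_n, e))
    fused.sort(key=lambda fe: (-fe[0], -fe[1].score, fe[1].doc_id))
    return [
        RunEntry(query_id=e.query_id, doc_id=e.doc_id, rank=r + 1, score=s, tag=tag)
        for r, (s, e) in enumerate(fused)
    ]


def rerank_run(
    corpus: Mapping[str, str],
    queries: Mapping[str, str],
    vocab: MDFVocabulary,
    ssm: SemanticSimilarityMatrix,
    cfg: SemRankConfig | None = None,
    net_cfg: NetworkConfig | None = None,
    tag: str = "SemRank",
    doc_annotations: Mapping[str, MDFAnnotation] | None = None,
    filter_dump: list | None = None,
) -> list[RunEntry]:
    """Full re-ranking run: BM25 candidates -> DMM scores -> fusion.

    Returns TREC-style run entries for all queries (queries with an empty
    baseline produce no entries and are logged).  ``filter_dump``, if a
    list, collects per-(query, doc) filter score rows for debugging.
    """
    if cfg is None:
        cfg = SemRankConfig()
    if net_cfg is None:
        net_cfg = NetworkConfig()
    if doc_annotations is None:
        doc_annotations = {doc_id: annotate(text, vocab) for doc_id, text in corpus.items()}
    stats = compute_statistics(doc_annotations.values())
    index = BM25Index(corpus, k1=cfg.bm25_k1, b=cfg.bm25_b)

    # Per-document quantities reused across queries.
    vec_cache: dict[str, np.ndarray] = {}
    nqm_cache: dict[str, object] = {}

    out: list[RunEntry] = []
    for query_id, query_text in queries.items():
        baseline = index.search(query_id, query_text, cfg.rerank_depth)
        if not baseline:
            logger.info("query %s: empty baseline result list", query_id)
            continue
        q_ann = annotate(query_text, vocab)
        Vq = to_binary_vector(q_ann, ssm.n)
        q_nqm = build_feature_matrix(Vq, ssm, owner="query")
        dmm: dict[str, float] = {}
        for entry in baseline:
            doc_id = entry.doc_id
            d_ann = doc_annotations[doc_id]
            if doc_id not in vec_cache:
                vec_cache[doc_id] = to_binary_vector(d_ann, ssm.n)
                nqm_cache[doc_id] = build_feature_matrix(
                    vec_cache[doc_id], ssm, owner="document"
                )
            scores = compute_filter_scores(
                FilterContext(
                    query=q_ann, document=d_ann, stats=stats, doc_rank=entry.rank
                ),
                fdqf_variant=cfg.fdqf_variant,
            )
            q_rep = represent(q_nqm, scores.query_vector(), Vq, net_cfg, owner="query")
            d_rep = represent(
                nqm_cache[doc_id],
                scores.document_vector(),
                vec_cache[doc_id],
                net_cfg,
                owner="document",
            )
            dmm[doc_id] = rsv_cosine(q_rep, d_rep)
            if filter_dump is not None:
                filter_dump.append((query_id, doc_id, scores))
        out.extend(semrank_fuse(baseline, dmm, cfg.alpha, tag=tag))
    return out
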