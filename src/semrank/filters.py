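"""The twelve scalar retrieval filters.

Six query-side filters (CoQF, LQF, RQF, PQF, PMIQF, FDQF) and six
document-side filters (CoDF, LDF, RDF, PDF, PMIDF, FDDF) summarize the
relationship between a query's MDF set Q and a document's MDF set D:

* confidence — corpus co-occurrence of the document's features with the
  query's features (CoQF) and plain overlap size (CoDF);
* length — overlap normalized by document length in MDFs (LQF requires
  the document to contain *all* query features, LDF does not);
* rank / organization — inverse baseline rank (RQF) and in-document query
  term frequency weighted by an order-preservation factor γ (RDF);
* proximity — inverse summed gap between query features inside the
  document (PQF) and inverse count of shared features (PDF);
* PMI — mean pointwise mutual information over feature pairs, with the
  collection size as N on the query side and the document length as N on
  the document side;
* feature difference — inverse count of query features missing from the
  document (FDQF) and of document features absent from the query (FDDF).

Set semantics (distinct features) apply everywhere except where positions
or within-document frequency are explicitly needed (PQF, RDF).  Every
filter is a total function: all zero-denominator / no-evidence cases
return 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus_stats import CorpusStatistics, UndefinedPMIError, pmi
from .vocabulary import MDFAnnotation

__all__ = [
    "FilterContext",
    "FilterScores",
    "QUERY_FILTER_NAMES",
    "DOCUMENT_FILTER_NAMES",
    "co_qf",
    "l_qf",
    "r_qf",
    "p_qf",
    "pmi_qf",
    "fd_qf",
    "co_df",
    "l_df",
    "r_df",
    "p_df",
    "pmi_df",
    "fd_df",
    "compute_filter_scores",
]

QUERY_FILTER_NAMES = ("co_qf", "l_qf", "r_qf", "p_qf", "pmi_qf", "fd_qf")
DOCUMENT_FILTER_NAMES = ("co_df", "l_df", "r_df", "p_df", "pmi_df", "fd_df")


@dataclass(frozen=True)
class FilterContext:
    """One (query, document) pair plus the collection evidence."""

    query: MDFAnnotation
    document: MDFAnnotation
    stats: CorpusStatistics
    doc_rank: int | None = None  # 1-based baseline rank, None if absent

    def __post_init__(self) -> None:
        if self.doc_rank is not None and self.doc_rank < 1:
            raise ValueError(f"doc_rank must be >= 1, got {self.doc_rank}")


@dataclass(frozen=True)
class FilterScores:
    """The six query-side and six document-side filter values."""

    co_qf: float
    l_qf: float
    r_qf: float
    p_qf: float
    pmi_qf: float
    fd_qf: float
    co_df: float
    l_df: float
    r_df: float
    p_df: float
    pmi_df: float
    fd_df: float

    def query_vector(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in QUERY_FILTER_NAMES])

    def document_vector(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in DOCUMENT_FILTER_NAMES])


# ---------------------------------------------------------------- query side


def co_qf(ctx: FilterContext) -> float:
    """Corpus co-occurrence of query MDFs with the document's MDFs.

    sum_{j in Q} sum_{i in D} codf(i, j) / sum_{i in D} df(i); 0 when the
    denominator vanishes.
    """
    Q, D, stats = ctx.query.distinct, ctx.document.distinct, ctx.stats
    denom = sum(stats.df(i) for i in D)
    if denom == 0:
        return 0.0
    num = sum(stats.codf(i, j) for j in Q for i in D)
    return num / denom


def l_qf(ctx: FilterContext) -> float:
    """|Q ∩ D| / |D| when the document contains all query MDFs, else 0."""
    Q, D = ctx.query.distinct, ctx.document.distinct
    if not Q or not D or not Q <= D:
        return 0.0
    return len(Q & D) / len(D)


def r_qf(ctx: FilterContext) -> float:
    """Inverse baseline document rank; 0 for documents the baseline missed."""
    if ctx.doc_rank is None:
        return 0.0
    return 1.0 / ctx.doc_rank


def p_qf(ctx: FilterContext) -> float:
    """Inverse summed gap between query-MDF occurrences in the document.

    The distance between two consecutive query-feature occurrences is the
    number of features strictly between them; PQF = 1 / (1 + sum of
    distances), 0 when no query feature occurs.
    """
    Q = ctx.query.distinct
    positions = [p for p, k in enumerate(ctx.document.occurrences) if k in Q]
    if not positions:
        return 0.0
    gaps = sum(b - a - 1 for a, b in zip(positions, positions[1:]))
    return 1.0 / (1.0 + gaps)


def pmi_qf(ctx: FilterContext) -> float:
    """Mean PMI over (document feature, query feature) pairs with evidence.

    Pairs with zero df or zero co-occurrence are skipped; 0 when no pair
    is defined.  N is the collection size.
    """
    Q, D, stats = ctx.query.distinct, ctx.document.distinct, ctx.stats
    vals = []
    for j in Q:
        for i in D:
            try:
                vals.append(pmi(i, j, stats))
            except UndefinedPMIError:
                continue
    return float(np.mean(vals)) if vals else 0.0


def fd_qf(ctx: FilterContext, variant: str = "missing") -> float:
    """Inverse count of query MDFs the document lacks: 1/(1 + |Q \\ D|).

    ``variant="intersection"`` exposes the alternative reading
    1/(1 + |Q ∩ D|) instead.
    """
    Q, D = ctx.query.distinct, ctx.document.distinct
    if variant == "missing":
        return 1.0 / (1.0 + len(Q - D))
    if variant == "intersection":
        return 1.0 / (1.0 + len(Q & D))
    raise ValueError(f"unknown fd_qf variant {variant!r}")


# ------------------------------------------------------------- document side


def co_df(ctx: FilterContext) -> float:
    """Number of MDFs common to query and document."""
    return float(len(ctx.query.distinct & ctx.document.distinct))


def l_df(ctx: FilterContext) -> float:
    """|Q ∩ D| divided by the document length in distinct MDFs; 0 if empty."""
    Q, D = ctx.query.distinct, ctx.document.distinct
    if not D:
        return 0.0
    return len(Q & D) / len(D)


def _is_subsequence(needle: Sequence[int], haystack: Sequence[int]) -> bool:
    it = iter(haystack)
    return all(any(h == x for h in it) for x in needle)


def r_df(ctx: FilterContext) -> float:
    """Within-document query term frequency times the organization factor γ.

    γ = 1 when the query's MDFs, in first-occurrence order, appear as a
    subsequence of the document's occurrence list (the query "preserves
    its organization"); γ = 0.5 otherwise.  0 when no query MDF occurs.
    """
    Q = ctx.query.distinct
    count = sum(1 for k in ctx.document.occurrences if k in Q)
    if count == 0:
        return 0.0
    gamma = (
        1.0
        if _is_subsequence(ctx.query.first_occurrence_order(), ctx.document.occurrences)
        else 0.5
    )
    return count * gamma


def p_df(ctx: FilterContext) -> float:
    """Inverse count of document MDFs that appear in the query; 0 if none."""
    shared = ctx.document.distinct & ctx.query.distinct
    if not shared:
        return 0.0
    return 1.0 / len(shared)


def pmi_df(ctx: FilterContext) -> float:
    """Mean PMI over unordered pairs of document MDFs, with N = |D| (length).

    Uses the document's occurrence count as the collection-size stand-in;
    pairs without co-occurrence evidence are skipped; 0 when no pair is
    defined.
    """
    D = sorted(ctx.document.distinct)
    n_doc = len(ctx.document.occurrences)
    vals = []
    for a in range(len(D)):
        for b in range(a + 1, len(D)):
            try:
                vals.append(pmi(D[a], D[b], ctx.stats, n_override=n_doc))
            except UndefinedPMIError:
                continue
    return float(np.mean(vals)) if vals else 0.0


def fd_df(ctx: FilterContext) -> float:
    """Inverse count of document MDFs absent from the query: 1/(1 + |D \\ Q|)."""
    Q, D = ctx.query.distinct, ctx.document.distinct
    return 1.0 / (1.0 + len(D - Q))


def compute_filter_scores(
    ctx: FilterContext, fdqf_variant: str = "missing"
) -> FilterScores:
    """Evaluate all twelve filters for one (query, document) pair."""
    return FilterScores(
        co_qf=co_qf(ctx),
        l_qf=l_qf(ctx),
        r_qf=r_qf(ctx),
        p_qf=p_qf(ctx),
        pmi_qf=pmi_qf(ctx),
        fd_qf=fd_qf(ctx, variant=fdqf_variant),
        co_df=co_df(ctx),
        l_df=l_df(ctx),
        r_df=r_df(ctx),
        p_df=p_df(ctx),
        pmi_df=pmi_df(ctx),
        fd_df=fd_df(ctx),
    )
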