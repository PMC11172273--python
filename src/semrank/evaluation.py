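"""TREC-style retrieval evaluation: qrels/run I/O, MAP, P@k, significance.

Conventions follow trec_eval: P@k divides by k even when fewer than k
documents were retrieved; average precision normalizes by the number of
relevant documents the qrels hold for the query; queries with no relevant
document are skipped from MAP (with a warning).  Relevance is binary:
grade > 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .ranking import RunEntry

__all__ = [
    "Qrels",
    "read_qrels",
    "write_qrels",
    "read_run",
    "write_run",
    "run_rankings",
    "precision_at_k",
    "average_precision",
    "mean_average_precision",
    "evaluate_run",
    "ComparisonResult",
    "compare_runs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Qrels:
    """Relevance judgments: (query_id, doc_id) -> integer grade >= 0."""

    judgments: Mapping[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (q, d), g in self.judgments.items():
            if g < 0:
                raise ValueError(f"negative relevance grade for ({q}, {d}): {g}")

    def is_relevant(self, query_id: str, doc_id: str) -> bool:
        return self.judgments.get((query_id, doc_id), 0) > 0

    def relevant_docs(self, query_id: str) -> set[str]:
        return {d for (q, d), g in self.judgments.items() if q == query_id and g > 0}

    def num_relevant(self, query_id: str) -> int:
        return sum(1 for (q, _), g in self.judgments.items() if q == query_id and g > 0)

    def query_ids(self) -> list[str]:
        return sorted({q for q, _ in self.judgments})


def read_qrels(path: str | Path) -> Qrels:
    """Read ``qid 0 docid rel`` whitespace-separated judgments."""
    judgments: dict[tuple[str, str], int] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        qid, _, docid, rel = line.split()
        judgments[(qid, docid)] = int(rel)
    return Qrels(judgments=judgments)


def write_qrels(qrels: Qrels, path: str | Path) -> None:
    lines = [
        f"{q} 0 {d} {g}" for (q, d), g in sorted(qrels.judgments.items())
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_run(path: str | Path) -> list[RunEntry]:
    """Read a TREC run file: ``qid Q0 docid rank score tag``."""
    entries = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        qid, _, docid, rank, score, tag = line.split()
        entries.append(
            RunEntry(query_id=qid, doc_id=docid, rank=int(rank), score=float(score), tag=tag)
        )
    return entries


def write_run(entries: Sequence[RunEntry], path: str | Path) -> None:
    lines = [
        f"{e.query_id} Q0 {e.doc_id} {e.rank} {e.score:.17g} {e.tag}" for e in entries
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def run_rankings(entries: Sequence[RunEntry]) -> dict[str, list[str]]:
    """Group run entries into per-query doc-id lists in rank order."""
    grouped: dict[str, list[RunEntry]] = {}
    for e in entries:
        grouped.setdefault(e.query_id, []).append(e)
    return {
        qid: [e.doc_id for e in sorted(es, key=lambda e: e.rank)]
        for qid, es in grouped.items()
    }


def precision_at_k(
    ranked_doc_ids: Sequence[str], qrels: Qrels, query_id: str, k: int
) -> float:
    """Fraction of the top k ranks holding a relevant document (divisor k)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    hits = sum(
        1 for d in ranked_doc_ids[:k] if qrels.is_relevant(query_id, d)
    )
    return hits / k


def average_precision(
    ranked_doc_ids: Sequence[str], qrels: Qrels, query_id: str
) -> float:
    """AP = (1/R) * sum over relevant ranks r of precision@r; 0 when R = 0."""
    R = qrels.num_relevant(query_id)
    if R == 0:
        return 0.0
    hits = 0
    total = 0.0
    for r, doc_id in enumerate(ranked_doc_ids, start=1):
        if qrels.is_relevant(query_id, doc_id):
            hits += 1
            total += hits / r
    return total / R


def _as_rankings(
    run: Sequence[RunEntry] | Mapping[str, Sequence[str]],
) -> dict[str, list[str]]:
    if isinstance(run, Mapping):
        return {q: list(docs) for q, docs in run.items()}
    return run_rankings(run)


def mean_average_precision(
    run: Sequence[RunEntry] | Mapping[str, Sequence[str]], qrels: Qrels
) -> float:
    """Unweighted mean of per-query AP over queries with at least one
    relevant document; queries without one are skipped with a warning."""
    rankings = _as_rankings(run)
    aps = []
    for qid, ranked in rankings.items():
        if qrels.num_relevant(qid) == 0:
            logger.warning("query %s has no relevant documents; skipped from MAP", qid)
            continue
        aps.append(average_precision(ranked, qrels, qid))
    if not aps:
        raise ValueError("no evaluable query: every query lacks relevant documents")
    return float(np.mean(aps))


def evaluate_run(
    run: Sequence[RunEntry] | Mapping[str, Sequence[str]],
    qrels: Qrels,
    ks: Sequence[int] = (5, 10),
) -> dict[str, float]:
    """MAP plus P@k (averaged over evaluable queries) for the given ks."""
    rankings = _as_rankings(run)
    evaluable = [q for q in rankings if qrels.num_relevant(q) > 0]
    out = {"map": mean_average_precision(run, qrels)}
    for k in ks:
        out[f"p{k}"] = float(
            np.mean([precision_at_k(rankings[q], qrels, q, k) for q in evaluable])
        )
    return out


@dataclass(frozen=True)
class ComparisonResult:
    """Paired per-query comparison of two runs."""

    metric: str
    per_query: dict[str, tuple[float, float]]
    deltas: dict[str, float]
    p_value: float | None
    significant: bool
    improvement_rate: float | None
    reason: str = ""


def _per_query_metric(
    rankings: Mapping[str, Sequence[str]], qrels: Qrels, metric: str
) -> dict[str, float]:
    out = {}
    for qid, ranked in rankings.items():
        if qrels.num_relevant(qid) == 0:
            continue
        if metric == "ap":
            out[qid] = average_precision(ranked, qrels, qid)
        elif metric.startswith("p"):
            out[qid] = precision_at_k(ranked, qrels, qid, int(metric[1:]))
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return out


def compare_runs(
    run_a: Sequence[RunEntry] | Mapping[str, Sequence[str]],
    run_b: Sequence[RunEntry] | Mapping[str, Sequence[str]],
    qrels: Qrels,
    metric: str = "ap",
) -> ComparisonResult:
    """Per-query deltas (B - A) and a two-sided Wilcoxon signed-rank test.

    Zero differences are dropped before the test; with fewer than two
    non-zero pairs the p-value is undefined and the comparison is
    reported as not significant with the reason.  The improvement rate is
    the mean relative gain (b - a)/a over queries where A is positive.
    """
    ra, rb = _as_rankings(run_a), _as_rankings(run_b)
    if set(ra) != set(rb):
        raise ValueError("runs cover different query sets")
    ma = _per_query_metric(ra, qrels, metric)
    mb = _per_query_metric(rb, qrels, metric)
    per_query = {q: (ma[q], mb[q]) for q in sorted(ma)}
    deltas = {q: b - a for q, (a, b) in per_query.items()}
    gains = [(b - a) / a for a, b in per_query.values() if a > 0]
    improvement = float(np.mean(gains)) if gains else None

    nonzero = [d for d in deltas.values() if d != 0.0]
    if len(nonzero) < 2:
        return ComparisonResult(
            metric=metric,
            per_query=per_query,
            deltas=deltas,
            p_value=None,
            significant=False,
            improvement_rate=improvement,
            reason=f"only {len(nonzero)} non-zero paired difference(s); "
            "Wilcoxon signed-rank test undefined",
        )
    a_vals = [per_query[q][0] for q in per_query]
    b_vals = [per_query[q][1] for q in per_query]
    res = sps.wilcoxon(
        b_vals, a_vals, zero_method="wilcox", alternative="two-sided"
    )
    p = float(res.pvalue)
    return ComparisonResult(
        metric=metric,
        per_query=per_query,
        deltas=deltas,
        p_value=p,
        significant=p < 0.05,
        improvement_rate=improvement,
    )
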