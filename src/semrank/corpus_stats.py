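"""Collection-level MDF frequency and co-occurrence statistics.

Counting is document-level presence/absence: a feature occurring three
times in one caption contributes one to its document frequency, and a
pair co-occurs once per document that contains both.  These counts feed
the confidence and pointwise-mutual-information filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import log
from typing import Iterable

from .vocabulary import MDFAnnotation

__all__ = ["CorpusStatistics", "compute_statistics", "pmi", "UndefinedPMIError"]


class UndefinedPMIError(ValueError):
    """PMI is undefined when any of df(i), df(j) or codf(i, j) is zero."""


@dataclass(frozen=True)
class CorpusStatistics:
    """Document frequencies, pair co-occurrence counts and collection size.

    ``codf`` stores unordered pairs ``(i, j)`` with ``i < j``; the diagonal
    co-occurrence ``codf(i, i)`` equals ``df(i)`` by construction and is
    served by the accessor rather than stored.
    """

    n_docs: int
    _df: dict[int, int] = field(default_factory=dict)
    _codf: dict[tuple[int, int], int] = field(default_factory=dict)

    def df(self, i: int) -> int:
        """Number of documents containing feature i."""
        return self._df.get(i, 0)

    def codf(self, i: int, j: int) -> int:
        """Number of documents containing both features (symmetric)."""
        if i == j:
            return self.df(i)
        key = (i, j) if i < j else (j, i)
        return self._codf.get(key, 0)

    def merge(self, other: "CorpusStatistics") -> "CorpusStatistics":
        """Statistics of the union of two disjoint document collections."""
        df = dict(self._df)
        for k, v in other._df.items():
            df[k] = df.get(k, 0) + v
        codf = dict(self._codf)
        for k, v in other._codf.items():
            codf[k] = codf.get(k, 0) + v
        return CorpusStatistics(self.n_docs + other.n_docs, df, codf)


def compute_statistics(annotations: Iterable[MDFAnnotation]) -> CorpusStatistics:
    """Presence-based df / co-df over a collection of annotated documents."""
    df: dict[int, int] = {}
    codf: dict[tuple[int, int], int] = {}
    n_docs = 0
    for ann in annotations:
        n_docs += 1
        present = sorted(ann.distinct)
        for i in present:
            df[i] = df.get(i, 0) + 1
        for i, j in combinations(present, 2):
            codf[(i, j)] = codf.get((i, j), 0) + 1
    return CorpusStatistics(n_docs=n_docs, _df=df, _codf=codf)


def pmi(
    i: int,
    j: int,
    stats: CorpusStatistics,
    n_override: int | None = None,
) -> float:
    """Pointwise mutual information ln(N * codf(i,j) / (df(i) * df(j))).

    ``n_override`` substitutes the collection size N (the document-side
    PMI filter uses the document length instead of the collection size);
    the frequency counts always come from the collection statistics.

    Raises
    ------
    UndefinedPMIError
        If df(i), df(j) or codf(i, j) is zero.  Callers aggregating over
        pairs must skip undefined pairs rather than coerce them to 0.
    """
    n = stats.n_docs if n_override is None else n_override
    d_i, d_j, co = stats.df(i), stats.df(j), stats.codf(i, j)
    if d_i <= 0 or d_j <= 0 or co <= 0 or n <= 0:
        raise UndefinedPMIError(
            f"PMI undefined for pair ({i}, {j}): df={d_i},{d_j} codf={co} N={n}"
        )
    return log(n * co / (d_i * d_j))
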