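"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the definitions by direct counting over
raw integer lists, deliberately sharing no code with the package: corpora
are plain lists of occurrence lists, statistics are recomputed on the fly,
and aggregates use explicit loops.
"""

from __future__ import annotations

import math


# ------------------------------------------------------------- statistics


def o_df(corpus: list[list[int]], f: int) -> int:
    return sum(1 for doc in corpus if f in set(doc))


def o_codf(corpus: list[list[int]], i: int, j: int) -> int:
    return sum(1 for doc in corpus if i in set(doc) and j in set(doc))


def o_pmi(corpus: list[list[int]], i: int, j: int, n: int | None = None) -> float | None:
    """None where PMI is undefined."""
    big_n = len(corpus) if n is None else n
    di, dj, co = o_df(corpus, i), o_df(corpus, j), o_codf(corpus, i, j)
    if di == 0 or dj == 0 or co == 0 or big_n <= 0:
        return None
    return math.log(big_n * co / (di * dj))


# ------------------------------------------------------------ the filters


def o_co_qf(corpus, q, d) -> float:
    denom = sum(o_df(corpus, i) for i in set(d))
    if denom == 0:
        return 0.0
    num = sum(o_codf(corpus, i, j) for j in set(q) for i in set(d))
    return num / denom


def o_l_qf(corpus, q, d) -> float:
    qs, ds = set(q), set(d)
    if qs and ds and qs.issubset(ds):
        return len(qs & ds) / len(ds)
    return 0.0


def o_r_qf(rank) -> float:
    return 0.0 if rank is None else 1.0 / rank


def o_p_qf(corpus, q, d) -> float:
    qs = set(q)
    pos = [p for p, f in enumerate(d) if f in qs]
    if not pos:
        return 0.0
    total = 0
    for a, b in zip(pos, pos[1:]):
        total += b - a - 1
    return 1.0 / (1.0 + total)


def o_pmi_qf(corpus, q, d) -> float:
    vals = []
    for j in set(q):
        for i in set(d):
            v = o_pmi(corpus, i, j)
            if v is not None:
                vals.append(v)
    return sum(vals) / len(vals) if vals else 0.0


def o_fd_qf(corpus, q, d) -> float:
    return 1.0 / (1.0 + len(set(q) - set(d)))


def o_co_df(corpus, q, d) -> float:
    return float(len(set(q) & set(d)))


def o_l_df(corpus, q, d) -> float:
    ds = set(d)
    if not ds:
        return 0.0
    return len(set(q) & ds) / len(ds)


def o_r_df(corpus, q, d) -> float:
    qs = set(q)
    count = sum(1 for f in d if f in qs)
    if count == 0:
        return 0.0
    order = []
    for f in q:
        if f not in order:
            order.append(f)
    # subsequence check by explicit scanning
    pos = 0
    ok = True
    for f in order:
        while pos < len(d) and d[pos] != f:
            pos += 1
        if pos == len(d):
            ok = False
            break
        pos += 1
    return count * (1.0 if ok else 0.5)


def o_p_df(corpus, q, d) -> float:
    shared = set(d) & set(q)
    return 1.0 / len(shared) if shared else 0.0


def o_pmi_df(corpus, q, d) -> float:
    ds = sorted(set(d))
    vals = []
    for x in range(len(ds)):
        for y in range(x + 1, len(ds)):
            v = o_pmi(corpus, ds[x], ds[y], n=len(d))
            if v is not None:
                vals.append(v)
    return sum(vals) / len(vals) if vals else 0.0


def o_fd_df(corpus, q, d) -> float:
    return 1.0 / (1.0 + len(set(d) - set(q)))


# (name, oracle, exact?) in the package's filter-vector order
QUERY_ORACLES = [
    ("co_qf", o_co_qf, True),
    ("l_qf", o_l_qf, True),
    ("p_qf", o_p_qf, True),
    ("pmi_qf", o_pmi_qf, False),
    ("fd_qf", o_fd_qf, True),
]
DOCUMENT_ORACLES = [
    ("co_df", o_co_df, True),
    ("l_df", o_l_df, True),
    ("r_df", o_r_df, True),
    ("p_df", o_p_df, True),
    ("pmi_df", o_pmi_df, False),
    ("fd_df", o_fd_df, True),
]


# ----------------------------------------------------------- IR metrics


def o_precision_at_k(ranked, relevant: set, k: int) -> float:
    hits = 0
    for doc in ranked[:k]:
        if doc in relevant:
            hits += 1
    return hits / k


def o_average_precision(ranked, relevant: set) -> float:
    if not relevant:
        return 0.0
    total = 0.0
    hits = 0
    for r, doc in enumerate(ranked):
        if doc in relevant:
            hits += 1
            total += hits / (r + 1)
    return total / len(relevant)


# --------------------------------------------------------------- fusion


def o_fuse(baseline: list[tuple[str, float]], dmm: dict[str, float], alpha: float):
    """10-line re-implementation of the fusion rule.

    ``baseline`` is [(doc_id, score)] in rank order; returns doc_ids in
    fused order.
    """
    mi = max(s for _, s in baseline)
    md = max((dmm.get(doc, 0.0) for doc, _ in baseline), default=0.0)
    rows = []
    for doc, s in baseline:
        ni = s / mi if mi > 0 else 0.0
        nd = dmm.get(doc, 0.0) / md if md > 0 else 0.0
        rows.append((-(alpha * ni + (1 - alpha) * nd), -s, doc))
    rows.sort()
    return [doc for _, _, doc in rows]
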