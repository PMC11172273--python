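"""Seeded generator of synthetic retrieval collections.

Emulates a text-based medical image collection at desk scale: each
"document" is an image caption built from a handful of MDF value strings
(drawn Zipf-style, so a few modalities dominate, as in real captions)
interleaved with filler tokens from a synthetic non-medical lexicon;
queries are one to three MDF values plus a couple of filler tokens.

Ground-truth relevance is driven by semantic MDF overlap: a document is
relevant to a query when the mean, over query features, of the best
semantic similarity to any document feature reaches a threshold tau —
exact feature matches count 1, same-category features count their
(boosted) similarity, unrelated features contribute little.  A label
noise rate epsilon flips each judgment independently, mimicking imperfect
human assessments.  The filler tokens carry lexical signal only the
baseline (BM25) can see, while the semantic overlap carries signal only
the matcher can exploit, so the fused re-ranker has room to beat both
limits.

Generation is a pure function of (config, seed): the same inputs yield
byte-identical corpus, query and qrels files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

from .evaluation import Qrels, write_qrels
from .semantics import SemanticSimilarityMatrix, save_similarity_matrix
from .vocabulary import MDFAnnotation, MDFVocabulary

__all__ = ["SynthConfig", "SyntheticCollection", "generate_collection", "overlap_score"]


class SynthConfigError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters.

    Defaults describe the reference study conditions used throughout the
    test suite: 500 captions, 20 queries, relevance threshold 0.6,
    5% label noise.
    """

    n_docs: int = 500
    n_queries: int = 20
    mdf_per_doc: tuple[int, int] = (2, 6)
    mdf_per_query: tuple[int, int] = (1, 3)
    filler_vocab_size: int = 200
    filler_per_doc: tuple[int, int] = (5, 15)
    filler_per_query: tuple[int, int] = (0, 2)
    relevance_threshold: float = 0.6
    label_noise: float = 0.05
    zipf_exponent: float = 1.0
    category_coherence: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mdf_per_doc", "mdf_per_query", "filler_per_doc", "filler_per_query"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise SynthConfigError(f"{name} range ({lo}, {hi}) is empty or negative")
        if not 0.0 <= self.label_noise <= 0.5:
            raise SynthConfigError("label_noise must lie in [0, 0.5]")
        if not (
            np.isfinite(self.relevance_threshold) and self.relevance_threshold >= 0.0
        ):
            raise SynthConfigError("relevance_threshold must be a non-negative real")
        if not 0.0 <= self.category_coherence <= 1.0:
            raise SynthConfigError("category_coherence must lie in [0, 1]")
        if self.n_docs < 1 or self.n_queries < 1:
            raise SynthConfigError("n_docs and n_queries must be >= 1")


@dataclass(frozen=True)
class SyntheticCollection:
    """A generated corpus with queries, judgments and provenance."""

    documents: dict[str, str]
    queries: dict[str, str]
    qrels: Qrels
    doc_features: dict[str, tuple[int, ...]]
    query_features: dict[str, tuple[int, ...]]
    config: SynthConfig

    def write(
        self,
        outdir: str | Path,
        ssm: SemanticSimilarityMatrix | None = None,
        vocab: MDFVocabulary | None = None,
    ) -> None:
        """Write corpus.jsonl, queries.jsonl, qrels.txt (and ssm.tsv)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "corpus.jsonl", "w", encoding="utf-8") as fh:
            for doc_id, text in self.documents.items():
                fh.write(json.dumps({"id": doc_id, "text": text}) + "\n")
        with open(outdir / "queries.jsonl", "w", encoding="utf-8") as fh:
            for qid, text in self.queries.items():
                fh.write(json.dumps({"id": qid, "text": text}) + "\n")
        write_qrels(self.qrels, outdir / "qrels.txt")
        if ssm is not None and vocab is not None:
            save_similarity_matrix(ssm, outdir / "ssm.tsv", vocab)


def overlap_score(
    q_features: MDFAnnotation | Iterable[int],
    d_features: MDFAnnotation | Iterable[int],
    ssm: SemanticSimilarityMatrix,
) -> float:
    """Best-match semantic overlap S(q, d).

    S = (1/|Q|) * sum over query features j of max over document features
    i of SSM[i, j]; 0 when either side is empty.  Monotone: adding
    document features never lowers S.
    """
    q = sorted(q_features.distinct if isinstance(q_features, MDFAnnotation) else set(q_features))
    d = sorted(d_features.distinct if isinstance(d_features, MDFAnnotation) else set(d_features))
    if not q or not d:
        return 0.0
    sub = ssm.values[np.ix_(d, q)]
    return float(sub.max(axis=0).mean())


def _zipf_probs(size: int, exponent: float) -> np.ndarray:
    """Zipf popularity over the support in its natural order.

    For the MDF catalogue this puts the mass on the leading radiology
    modalities (ultrasound, MRI, CT, X-ray, ...), which is how real
    caption collections are skewed.
    """
    p = np.arange(1, size + 1, dtype=float) ** -exponent
    return p / p.sum()


def generate_collection(
    cfg: SynthConfig,
    vocab: MDFVocabulary,
    ssm: SemanticSimilarityMatrix,
) -> SyntheticCollection:
    """Generate a corpus, query set and qrels under the config's model."""
    if ssm.n != vocab.n:
        raise SynthConfigError(
            f"similarity matrix size {ssm.n} does not match vocabulary size {vocab.n}"
        )
    rng = np.random.default_rng(cfg.seed)
    n = vocab.n
    mdf_p = _zipf_probs(n, cfg.zipf_exponent)
    filler_lexicon = [f"flr{i:03d}" for i in range(cfg.filler_vocab_size)]
    filler_p = _zipf_probs(cfg.filler_vocab_size, cfg.zipf_exponent)
    # A feature is written as any of its surface forms with equal chance:
    # a caption says "MRI" or "Magnetic Resonance Imaging" interchangeably.
    # The annotator resolves every form to the same concept index, while a
    # token matcher sees unrelated strings — the lexical gap the semantic
    # pipeline is meant to bridge.
    surface_forms = [
        (vocab.canonical(i), *vocab.synonyms.get(vocab.canonical(i), ()))
        for i in range(n)
    ]
    cats = vocab.category_index
    n_cats = len(vocab.categories)
    # Popularity of a category is the summed popularity of its features.
    cat_p = np.array([mdf_p[cats == c].sum() for c in range(n_cats)])
    cat_p /= cat_p.sum()

    def _sample_features(k: int, coherent: bool) -> tuple[int, ...]:
        """Feature draw for one item.

        Captions (``coherent=True``) follow the Zipf popularity and are
        topically coherent: a caption about one exam lists several
        attributes of the same facet, so a share ``category_coherence``
        of the probability mass is concentrated on a focus category.
        This makes semantically close features co-occur, the structure
        the co-occurrence and PMI filters assume.  Queries
        (``coherent=False``) draw uniformly: topic sets span the
        catalogue instead of mirroring caption frequencies.
        """
        if k <= 0:
            return ()
        p = mdf_p if coherent else np.full(n, 1.0 / n)
        if coherent and cfg.category_coherence > 0:
            focus = int(rng.choice(n_cats, p=cat_p))
            mask = cats == focus
            within = np.where(mask, mdf_p, 0.0)
            within /= within.sum()
            p = cfg.category_coherence * within + (1 - cfg.category_coherence) * mdf_p
        return tuple(sorted(int(i) for i in rng.choice(n, size=k, replace=False, p=p)))

    def _sample_text(mdf_range, filler_range, coherent) -> tuple[str, tuple[int, ...]]:
        k = min(int(rng.integers(mdf_range[0], mdf_range[1] + 1)), n)
        feats = _sample_features(k, coherent)
        nf = int(rng.integers(filler_range[0], filler_range[1] + 1))
        words = [
            surface_forms[i][int(rng.integers(len(surface_forms[i])))] for i in feats
        ] + [
            filler_lexicon[int(i)]
            for i in rng.choice(cfg.filler_vocab_size, size=nf, replace=True, p=filler_p)
        ]
        rng.shuffle(words)
        return " ".join(words), feats

    documents: dict[str, str] = {}
    doc_features: dict[str, tuple[int, ...]] = {}
    for i in range(cfg.n_docs):
        doc_id = f"doc{i:05d}"
        documents[doc_id], doc_features[doc_id] = _sample_text(
            cfg.mdf_per_doc, cfg.filler_per_doc, coherent=True
        )

    queries: dict[str, str] = {}
    query_features: dict[str, tuple[int, ...]] = {}
    for i in range(cfg.n_queries):
        qid = f"q{i:03d}"
        # Queries span facets freely (a clinician combines modality and
        # condition), so they draw from the global popularity alone.
        queries[qid], query_features[qid] = _sample_text(
            cfg.mdf_per_query, cfg.filler_per_query, coherent=False
        )

    judgments: dict[tuple[str, str], int] = {}
    for qid in queries:
        for doc_id in documents:
            s = overlap_score(query_features[qid], doc_features[doc_id], ssm)
            rel = s >= cfg.relevance_threshold
            if cfg.label_noise > 0 and rng.random() < cfg.label_noise:
                rel = not rel
            if rel:
                judgments[(qid, doc_id)] = 1
    return SyntheticCollection(
        documents=documents,
        queries=queries,
        qrels=Qrels(judgments=judgments),
        doc_features=doc_features,
        query_features=query_features,
        config=cfg,
    )
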