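"""Semantic similarity matrix (SSM) handling and feature-matrix construction.

The SSM holds one similarity per unordered pair of MDF values.  In the
intended deployment it comes from an ontology-based measure (e.g. Resnik
information-content similarity over UMLS concepts) computed offline and
exported as TSV; raw values from such tools are unbounded and occasionally
asymmetric, so loading symmetrizes by averaging and min-max normalizes the
off-diagonal entries to [0, 1] with the diagonal forced to 1.

A seeded fixture generator stands in where no ontology export is
available: it draws low baseline similarities and boosts pairs belonging
to the same MDF category, which mimics the locality of an ontology
(features under one heading are more alike than features across headings).

An item (query or document) with binary presence vector V is represented
by the feature matrix ``NQM[i][j] = M[i][j] * SSM[i][j]`` where
``M[i][j] = V[i]`` is the row-constant broadcast of V: the rows of active
features carry their similarity profile to every feature, inactive rows
are zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .vocabulary import MDFVocabulary

__all__ = [
    "SemanticSimilarityMatrix",
    "FeatureMatrix",
    "load_similarity_matrix",
    "save_similarity_matrix",
    "fixture_similarity_matrix",
    "build_feature_matrix",
]


class SimilarityMatrixError(ValueError):
    """Raised for malformed or inconsistent similarity matrix inputs."""


@dataclass(frozen=True)
class SemanticSimilarityMatrix:
    """n x n symmetric non-negative matrix of pairwise feature similarities.

    Normalized construction paths (the loader's default and the fixture
    generator) guarantee entries in [0, 1] with unit diagonal; an
    unnormalized load keeps the raw scale.
    """

    values: np.ndarray
    provenance: str = "external"

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise SimilarityMatrixError(f"similarity matrix must be square, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-12):
            raise SimilarityMatrixError("similarity matrix must be symmetric")
        if np.any(~np.isfinite(v)) or np.any(v < -1e-12):
            raise SimilarityMatrixError("similarity entries must be finite and non-negative")


@dataclass(frozen=True)
class FeatureMatrix:
    """NQM = (row-constant broadcast of V) * SSM, elementwise."""

    values: np.ndarray
    owner: str = "query"

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _normalize(raw: np.ndarray) -> np.ndarray:
    """Symmetrize by averaging, min-max scale off-diagonal, force diag to 1."""
    sym = (raw + raw.T) / 2.0
    n = sym.shape[0]
    out = sym.astype(float).copy()
    if n > 1:
        off = ~np.eye(n, dtype=bool)
        lo, hi = out[off].min(), out[off].max()
        if hi > lo:
            out[off] = (out[off] - lo) / (hi - lo)
        else:
            # Constant off-diagonal: keep zeros at 0, saturate anything else.
            out[off] = 1.0 if hi > 0 else 0.0
    np.fill_diagonal(out, 1.0)
    return out


def load_similarity_matrix(
    path: str | Path,
    vocab: MDFVocabulary,
    normalize: bool = True,
) -> SemanticSimilarityMatrix:
    """Load a TSV of raw pairwise similarities keyed by canonical value names.

    The first row and first column carry canonical value names; they must
    cover the whole vocabulary (extra rows/columns are ignored).  Raw
    entries must be non-negative; with ``normalize`` (the default) they are
    symmetrized, min-max scaled to [0, 1] over the off-diagonal, and the
    diagonal is forced to 1.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    names = [value for _, value in vocab.values]
    missing = sorted(
        set(names) - (set(frame.index) & set(frame.columns))
    )
    if missing:
        raise SimilarityMatrixError(
            f"similarity file is missing vocabulary values: {missing}"
        )
    raw = frame.loc[names, names].to_numpy(dtype=float)
    if np.any(~np.isfinite(raw)):
        raise SimilarityMatrixError("similarity file contains non-finite entries")
    if np.any(raw < 0):
        raise SimilarityMatrixError("similarity entries must be non-negative")
    if normalize:
        values = _normalize(raw)
    else:
        values = (raw + raw.T) / 2.0
    return SemanticSimilarityMatrix(values=values, provenance="external")


def save_similarity_matrix(
    ssm: SemanticSimilarityMatrix, path: str | Path, vocab: MDFVocabulary
) -> None:
    """Write the matrix as TSV with canonical value names on both axes."""
    names = [value for _, value in vocab.values]
    frame = pd.DataFrame(ssm.values, index=names, columns=names)
    frame.to_csv(path, sep="\t", float_format="%.17g")


def fixture_similarity_matrix(
    vocab: MDFVocabulary,
    seed: int,
    within_category_boost: float = 0.5,
) -> SemanticSimilarityMatrix:
    """Seeded synthetic SSM with ontology-like category locality.

    Baseline pairwise similarities are drawn from Beta(1, 12) — heavily
    right-skewed with mean ~0.08, mirroring how normalized
    information-content similarities behave: most concept pairs share
    almost nothing.  Pairs of features in the same MDF category get
    ``within_category_boost`` added before clipping to [0, 1], modelling
    ontology neighbourhoods.  The diagonal is 1.  Deterministic for a
    given (vocab, seed, boost).
    """
    if not 0.0 <= within_category_boost <= 1.0:
        raise SimilarityMatrixError("within_category_boost must lie in [0, 1]")
    n = vocab.n
    rng = np.random.default_rng(seed)
    base = rng.beta(1.0, 12.0, size=(n, n))
    sym = (base + base.T) / 2.0
    cats = vocab.category_index
    same_cat = cats[:, None] == cats[None, :]
    sym = np.where(same_cat, sym + within_category_boost, sym)
    sym = np.clip(sym, 0.0, 1.0)
    np.fill_diagonal(sym, 1.0)
    return SemanticSimilarityMatrix(values=sym, provenance="fixture")


def build_feature_matrix(
    V: np.ndarray, ssm: SemanticSimilarityMatrix, owner: str = "query"
) -> FeatureMatrix:
    """NQM[i][j] = V[i] * SSM[i][j] (M is the row-constant broadcast of V)."""
    V = np.asarray(V, dtype=float)
    if V.ndim != 1 or V.shape[0] != ssm.n:
        raise SimilarityMatrixError(
            f"binary vector of length {V.shape} does not match matrix size {ssm.n}"
        )
    return FeatureMatrix(values=V[:, None] * ssm.values, owner=owner)
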