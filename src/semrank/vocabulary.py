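"""Medical-Dependent Feature (MDF) vocabulary and text annotation.

Queries and image captions are reduced to a fixed catalogue of categorical
medical features — imaging modality, microscopy type, colour, test and
condition specifics.  The catalogue is ordered: every (category, value)
pair owns a dense integer index that all downstream vectors and matrices
are keyed on, so the same source file always yields the same indexing.

Free text is mapped onto the catalogue by deterministic dictionary
matching: case-insensitive, on token boundaries, longest match first, with
shorter matches nested inside an accepted longer match suppressed
("Transmission Microscopy" must not also fire a bare "Microscopy" entry).
A shipped synonym table covers common clinical abbreviations (MRI, CT,
EEG, ...).  This is a lightweight, fully reproducible stand-in for
concept-extraction services such as MetaMap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import cached_property
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "VocabularyError",
    "MDFVocabulary",
    "MDFAnnotation",
    "load_vocabulary",
    "vocabulary_from_mapping",
    "annotate",
    "to_binary_vector",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def _tokens(text: str) -> list[str]:
    """Lowercased alphanumeric tokens; punctuation acts as a boundary."""
    return _TOKEN_RE.findall(text.lower())


class VocabularyError(ValueError):
    """Raised for malformed vocabulary definitions or inconsistent indices."""


@dataclass(frozen=True)
class MDFVocabulary:
    """Ordered catalogue of (category, value) feature pairs.

    Attributes
    ----------
    categories : tuple of str
        Category names in source order.
    values : tuple of (str, str)
        ``(category, canonical value)`` pairs in source order; position in
        this tuple is the feature index.
    synonyms : mapping
        Canonical value -> tuple of surface forms (not including the
        canonical string itself).
    index : mapping
        Canonical value -> dense integer index in ``[0, n)``.
    """

    categories: tuple[str, ...]
    values: tuple[tuple[str, str], ...]
    synonyms: Mapping[str, tuple[str, ...]]
    index: Mapping[str, int]

    @property
    def n(self) -> int:
        """Number of feature values (the dimension of all MDF vectors)."""
        return len(self.values)

    def category_of(self, k: int) -> str:
        return self.values[k][0]

    def canonical(self, k: int) -> str:
        return self.values[k][1]

    @cached_property
    def category_index(self) -> np.ndarray:
        """Integer category label per feature index (for locality fixtures)."""
        order = {c: i for i, c in enumerate(self.categories)}
        return np.array([order[c] for c, _ in self.values], dtype=np.intp)

    @cached_property
    def _surface_table(self) -> dict[tuple[str, ...], int]:
        """Token-tuple of every surface form -> feature index."""
        table: dict[tuple[str, ...], int] = {}
        for category, value in self.values:
            k = self.index[value]
            for form in (value, *self.synonyms.get(value, ())):
                toks = tuple(_tokens(form))
                if not toks:
                    raise VocabularyError(
                        f"surface form {form!r} of {value!r} has no tokens"
                    )
                prev = table.setdefault(toks, k)
                if prev != k:
                    raise VocabularyError(
                        f"surface form {form!r} maps to both "
                        f"{self.values[prev][1]!r} and {value!r}"
                    )
        return table

    @cached_property
    def _max_form_len(self) -> int:
        return max(len(t) for t in self._surface_table)

    def to_mapping(self) -> dict:
        """Plain nested-dict form, invertible by ``vocabulary_from_mapping``."""
        cats: dict[str, dict[str, list[str]]] = {}
        for category in self.categories:
            cats[category] = {}
        for category, value in self.values:
            cats[category][value] = list(self.synonyms.get(value, ()))
        return {"categories": cats}

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_mapping(), sort_keys=False, allow_unicode=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml(), encoding="utf-8")


@dataclass(frozen=True)
class MDFAnnotation:
    """Ordered occurrence list of vocabulary indices extracted from a text.

    Duplicates are retained in text order because the proximity and
    organization filters need positions; ``distinct`` is the set view used
    by the set-semantics filters.
    """

    occurrences: tuple[int, ...]

    @cached_property
    def distinct(self) -> frozenset[int]:
        return frozenset(self.occurrences)

    def __len__(self) -> int:
        return len(self.occurrences)

    def first_occurrence_order(self) -> tuple[int, ...]:
        """Distinct indices ordered by their first appearance."""
        seen: dict[int, None] = {}
        for k in self.occurrences:
            seen.setdefault(k, None)
        return tuple(seen)


def vocabulary_from_mapping(mapping: Mapping) -> MDFVocabulary:
    """Build a vocabulary from the nested-dict form of the YAML layout.

    ``{"categories": {<name>: {<canonical>: [synonyms...]}}}``.  Category
    and value order is the mapping's insertion order, which fixes the
    dense index.
    """
    try:
        cat_block = mapping["categories"]
    except (KeyError, TypeError) as exc:
        raise VocabularyError("vocabulary mapping must have a 'categories' block") from exc
    if not cat_block:
        raise VocabularyError("vocabulary has no categories")

    categories: list[str] = []
    values: list[tuple[str, str]] = []
    synonyms: dict[str, tuple[str, ...]] = {}
    index: dict[str, int] = {}
    for category, value_block in cat_block.items():
        categories.append(str(category))
        if not value_block:
            raise VocabularyError(f"category {category!r} has no values")
        for value, syns in value_block.items():
            value = str(value)
            if value in index:
                raise VocabularyError(f"duplicate canonical value {value!r}")
            index[value] = len(values)
            values.append((str(category), value))
            synonyms[value] = tuple(str(s) for s in (syns or ()))

    vocab = MDFVocabulary(
        categories=tuple(categories),
        values=tuple(values),
        synonyms=synonyms,
        index=index,
    )
    vocab._surface_table  # validate surface forms eagerly
    return vocab


def load_vocabulary(source: str | Path | None = None) -> MDFVocabulary:
    """Load an MDF vocabulary.

    Parameters
    ----------
    source : path or None
        ``None`` (or ``"default"``) loads the packaged default catalogue
        of 9 categories / 87 values; otherwise ``source`` is a YAML file
        in the ``categories -> {value: [synonyms]}`` layout.
    """
    if source is None or source == "default":
        text = (
            resources.files("semrank.data")
            .joinpath("mdf_vocabulary.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(source).read_text(encoding="utf-8")
    mapping = yaml.safe_load(text)
    return vocabulary_from_mapping(mapping)


def annotate(text: str, vocab: MDFVocabulary) -> MDFAnnotation:
    """Map free text to an ordered list of MDF indices.

    Scans tokens left to right; at each position the longest surface form
    (canonical value or synonym) that matches is accepted and the scan
    resumes after it, so shorter forms nested inside an accepted match are
    suppressed.  Matching is case-insensitive and punctuation-blind.
    """
    toks = _tokens(text)
    if not toks:
        return MDFAnnotation(occurrences=())
    table = vocab._surface_table
    max_len = vocab._max_form_len
    occurrences: list[int] = []
    pos = 0
    n_toks = len(toks)
    while pos < n_toks:
        matched = False
        for length in range(min(max_len, n_toks - pos), 0, -1):
            k = table.get(tuple(toks[pos : pos + length]))
            if k is not None:
                occurrences.append(k)
                pos += length
                matched = True
                break
        if not matched:
            pos += 1
    return MDFAnnotation(occurrences=tuple(occurrences))


def to_binary_vector(
    ann: MDFAnnotation, vocab: MDFVocabulary | int
) -> np.ndarray:
    """Presence/absence vector V of length n: V[k] = 1 iff k occurs in ann.

    ``vocab`` may be a vocabulary or a bare dimension (handy when only the
    similarity matrix is around).
    """
    n = vocab if isinstance(vocab, int) else vocab.n
    v = np.zeros(n, dtype=float)
    for k in ann.distinct:
        if not 0 <= k < n:
            raise VocabularyError(
                f"annotation index {k} out of range for vocabulary of size {n}"
            )
        v[k] = 1.0
    return v
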