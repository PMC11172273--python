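from types import SimpleNamespace

import pytest

from semrank.corpus_stats import compute_statistics
from semrank.vocabulary import MDFAnnotation, load_vocabulary, vocabulary_from_mapping


@pytest.fixture(scope="session")
def default_vocab():
    return load_vocabulary()


@pytest.fixture(scope="session")
def ref():
    """Tiny hand-countable reference corpus.

    Four features a..d (indices 0..3) and three documents
    D1=[a,b], D2=[b,c], D3=[a,c,d], giving df: a=2,b=2,c=2,d=1 and codf:
    (a,b)=1,(b,c)=1,(a,c)=1,(a,d)=1,(c,d)=1,(b,d)=0.
    """
    vocab = vocabulary_from_mapping(
        {"categories": {"K": {"a": [], "b": [], "c": [], "d": []}}}
    )
    d1 = MDFAnnotation((0, 1))
    d2 = MDFAnnotation((1, 2))
    d3 = MDFAnnotation((0, 2, 3))
    docs = [d1, d2, d3]
    return SimpleNamespace(
        vocab=vocab,
        docs=docs,
        d1=d1,
        d2=d2,
        d3=d3,
        stats=compute_statistics(docs),
        raw=[[0, 1], [1, 2], [0, 2, 3]],
        a=0,
        b=1,
        c=2,
        d=3,
    )
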