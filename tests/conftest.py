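import pytest

from salnlp.corpus_io import LabeledSentence
from salnlp.synthetic_data import SynthConfig, generate_corpus
from salnlp.taxonomy import load_taxonomy


@pytest.fixture(scope="session")
def taxonomy():
    return load_taxonomy()


@pytest.fixture(scope="session")
def small_corpus(taxonomy):
    """30 deterministic synthetic articles with gold sentence labels."""
    return generate_corpus(SynthConfig(n_articles=30, seed=11), taxonomy)


@pytest.fixture(scope="session")
def medium_corpus(taxonomy):
    """120 deterministic synthetic articles, enough for split + training."""
    return generate_corpus(SynthConfig(n_articles=120, seed=7), taxonomy)


def make_sentence(
    text: str,
    fine: frozenset[str] | set[str] = frozenset(),
    top: frozenset[str] | set[str] | None = None,
    article_id: str = "A1",
    section_index: int = 0,
    start: int = 0,
    top_header: str = "Discussion",
    innermost_header: str = "Limitations",
) -> LabeledSentence:
    tax = load_taxonomy()
    fine = frozenset(fine)
    top = frozenset(top) if top is not None else tax.coarsen(fine)
    return LabeledSentence(
        article_id=article_id,
        section_index=section_index,
        char_start=start,
        char_end=start + len(text),
        text=text,
        top_header=top_header,
        innermost_header=innermost_header,
        is_sal=bool(fine or top),
        types_fine=fine,
        types_top=top,
    )
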