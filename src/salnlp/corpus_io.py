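"""Corpus handling: articles, BRAT standoff annotations, sentence
extraction from limitation-relevant sections, span-to-sentence label
projection, JSON Lines serialization, and article-level splits.

Offsets are 0-based and end-exclusive everywhere (the BRAT convention).
A :class:`SentenceRecord` produced by :func:`extract_sentences` carries
offsets into its section body; :func:`to_document_frame` shifts records
into the flattened-document frame used by BRAT files, so that spans and
sentences can be overlapped in a single coordinate system.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .taxonomy import Taxonomy
from .textproc import segment_sentences

__all__ = [
    "Section",
    "Article",
    "SentenceRecord",
    "SpanAnnotation",
    "LabeledSentence",
    "BratParseError",
    "DEFAULT_SECTION_KEYWORDS",
    "parse_brat",
    "select_limitation_sections",
    "extract_sentences",
    "flatten_article",
    "to_document_frame",
    "project_spans_to_sentences",
    "split_corpus",
    "read_sentences",
    "write_sentences",
    "read_articles",
    "write_articles",
]

#: Header keywords marking discussion- and limitation-related sections.
DEFAULT_SECTION_KEYWORDS = (
    "discussion",
    "limitation",
    "weakness",
    "conclusion",
    "caveat",
    "shortcoming",
    "drawback",
)


@dataclass(frozen=True)
class Section:
    top_header: str
    innermost_header: str
    body: str


@dataclass
class Article:
    article_id: str
    sections: list[Section]
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SentenceRecord:
    article_id: str
    section_index: int
    char_start: int
    char_end: int
    text: str
    top_header: str
    innermost_header: str


@dataclass(frozen=True)
class SpanAnnotation:
    article_id: str
    char_start: int
    char_end: int
    category: str
    annotator_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.char_start < self.char_end):
            raise ValueError(
                f"invalid span offsets ({self.char_start}, {self.char_end})"
            )


@dataclass(frozen=True)
class LabeledSentence(SentenceRecord):
    is_sal: bool = False
    types_fine: frozenset[str] = frozenset()
    types_top: frozenset[str] = frozenset()


class BratParseError(ValueError):
    pass


def parse_brat(
    document_text: str,
    annotation_text: str,
    *,
    taxonomy: Taxonomy | None = None,
    article_id: str = "",
    annotator_id: str = "",
) -> list[SpanAnnotation]:
    """Parse BRAT standoff text-bound ("T") lines against their document.

    Each line has the form ``T<i>\\t<Label> <start> <end>\\t<surface>``.
    The surface string must equal the document slice; a mismatch raises
    :class:`BratParseError` naming the line.  Unknown labels raise when a
    taxonomy is supplied.  Non-text-bound lines (events, notes) are
    ignored.
    """
    spans: list[SpanAnnotation] = []
    for lineno, raw in enumerate(annotation_text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line or not line.startswith("T"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise BratParseError(f"line {lineno}: malformed text-bound line: {line!r}")
        try:
            label, s_str, e_str = parts[1].split(" ")
            start, end = int(s_str), int(e_str)
        except ValueError:
            raise BratParseError(
                f"line {lineno}: cannot parse label/offsets from {parts[1]!r}"
            ) from None
        surface = parts[2] if len(parts) > 2 else ""
        if not (0 <= start < end <= len(document_text)):
            raise BratParseError(
                f"line {lineno}: offsets ({start}, {end}) outside document of "
                f"length {len(document_text)}"
            )
        if document_text[start:end] != surface:
            raise BratParseError(
                f"line {lineno}: surface {surface!r} does not match document "
                f"slice {document_text[start:end]!r}"
            )
        if taxonomy is not None and not taxonomy.validate_label(label, "fine"):
            raise BratParseError(f"line {lineno}: unknown category {label!r}")
        spans.append(
            SpanAnnotation(
                article_id=article_id,
                char_start=start,
                char_end=end,
                category=label,
                annotator_id=annotator_id,
            )
        )
    return spans


def _is_abstract(article: Article, idx: int) -> bool:
    sec = article.sections[idx]
    if sec.top_header.strip().lower() == "abstract":
        return True
    return idx == 0 and bool(article.metadata.get("first_section_is_abstract"))


def select_limitation_sections(
    article: Article,
    keywords: Sequence[str] = DEFAULT_SECTION_KEYWORDS,
    *,
    include_abstract: bool = True,
) -> list[int]:
    """Indices of the abstract plus discussion/limitation-related sections.

    A section qualifies when its top or innermost header contains any
    keyword as a case-insensitive substring (so "Limitations" and
    "Strengths and weaknesses" both match).
    """
    kws = [k.lower() for k in keywords]
    out: list[int] = []
    for idx, sec in enumerate(article.sections):
        headers = (sec.top_header.lower(), sec.innermost_header.lower())
        if include_abstract and _is_abstract(article, idx):
            out.append(idx)
        elif any(k in h for k in kws for h in headers):
            out.append(idx)
    return out


def extract_sentences(
    article: Article, section_indices: Iterable[int] | None = None
) -> list[SentenceRecord]:
    """Segment the given sections (default: all) into sentence records.

    Offsets are within each section body.
    """
    idxs = list(section_indices) if section_indices is not None else range(len(article.sections))
    records: list[SentenceRecord] = []
    for idx in idxs:
        sec = article.sections[idx]
        for s, e in segment_sentences(sec.body):
            records.append(
                SentenceRecord(
                    article_id=article.article_id,
                    section_index=idx,
                    char_start=s,
                    char_end=e,
                    text=sec.body[s:e],
                    top_header=sec.top_header,
                    innermost_header=sec.innermost_header,
                )
            )
    return records


def flatten_article(article: Article) -> tuple[str, list[int]]:
    """Flatten an article to a single document text (the BRAT ``.txt``).

    Returns the text and, per section, the offset of the section *body*
    within it.  Headers are emitted on their own lines before each body.
    """
    parts: list[str] = []
    body_offsets: list[int] = []
    pos = 0
    for sec in article.sections:
        header_block = f"{sec.top_header}\n{sec.innermost_header}\n"
        parts.append(header_block)
        pos += len(header_block)
        body_offsets.append(pos)
        parts.append(sec.body + "\n\n")
        pos += len(sec.body) + 2
    return "".join(parts), body_offsets


def to_document_frame(
    article: Article, records: Sequence[SentenceRecord]
) -> list[SentenceRecord]:
    """Shift section-frame sentence records into the flattened-document frame."""
    _, body_offsets = flatten_article(article)
    return [
        replace(
            r,
            char_start=r.char_start + body_offsets[r.section_index],
            char_end=r.char_end + body_offsets[r.section_index],
        )
        for r in records
    ]


def project_spans_to_sentences(
    sentences: Sequence[SentenceRecord],
    spans: Sequence[SpanAnnotation],
    taxonomy: Taxonomy,
    *,
    document_length: int | None = None,
) -> list[LabeledSentence]:
    """Consolidate span annotations into sentence-level multi-label records.

    A sentence receives the deduplicated categories of every span that
    overlaps it by at least one character; a span straddling a boundary
    labels both sentences.  Top-level sets are derived by coarsening.
    Spans and sentences must share one coordinate frame.
    """
    if document_length is not None:
        for sp in spans:
            if sp.char_end > document_length:
                raise ValueError(
                    f"span ({sp.char_start}, {sp.char_end}) outside document "
                    f"of length {document_length}"
                )
    out: list[LabeledSentence] = []
    for rec in sentences:
        fine: set[str] = set()
        for sp in spans:
            if sp.article_id and rec.article_id and sp.article_id != rec.article_id:
                continue
            if sp.char_start < rec.char_end and rec.char_start < sp.char_end:
                fine.add(sp.category)
        top = taxonomy.coarsen(fine)
        out.append(
            LabeledSentence(
                article_id=rec.article_id,
                section_index=rec.section_index,
                char_start=rec.char_start,
                char_end=rec.char_end,
                text=rec.text,
                top_header=rec.top_header,
                innermost_header=rec.innermost_header,
                is_sal=bool(fine),
                types_fine=frozenset(fine),
                types_top=top,
            )
        )
    return out


def split_corpus(
    articles: Sequence[Article],
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[list[Article], list[Article], list[Article]]:
    """Article-level train/dev/test split, deterministic for a fixed seed.

    Dev and test sizes are ``floor(ratio * n)``; the remainder goes to the
    training split, so 200 articles at (0.6, 0.2, 0.2) yield 120/40/40.
    """
    if len(articles) < 3:
        raise ValueError("need at least 3 articles to split")
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-6:
        raise ValueError(f"ratios must be positive and sum to 1, got {ratios}")
    n = len(articles)
    n_dev = int(ratios[1] * n)
    n_test = int(ratios[2] * n)
    n_train = n - n_dev - n_test
    order = sorted(range(n), key=lambda i: articles[i].article_id)
    random.Random(seed).shuffle(order)
    train = [articles[i] for i in order[:n_train]]
    dev = [articles[i] for i in order[n_train : n_train + n_dev]]
    test = [articles[i] for i in order[n_train + n_dev :]]
    return train, dev, test


# ---------------------------------------------------------------------------
# JSON Lines serialization
# ---------------------------------------------------------------------------

_REQUIRED_SENTENCE_FIELDS = (
    "article_id", "section_index", "char_start", "char_end",
    "text", "top_header", "innermost_header", "is_sal",
    "types_fine", "types_top",
)


def write_sentences(path: str | Path, records: Iterable[LabeledSentence]) -> None:
    """One JSON object per line; label sets serialized as sorted lists."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            obj = asdict(rec)
            obj["types_fine"] = sorted(rec.types_fine)
            obj["types_top"] = sorted(rec.types_top)
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def read_sentences(path: str | Path) -> list[LabeledSentence]:
    out: list[LabeledSentence] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: line {lineno}: invalid JSON: {exc}") from None
            missing = [f for f in _REQUIRED_SENTENCE_FIELDS if f not in obj]
            if missing:
                raise ValueError(
                    f"{path}: line {lineno}: record missing field(s) {missing}"
                )
            obj["types_fine"] = frozenset(obj["types_fine"])
            obj["types_top"] = frozenset(obj["types_top"])
            out.append(LabeledSentence(**obj))
    return out


def write_articles(path: str | Path, articles: Iterable[Article]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for art in articles:
            obj = {
                "article_id": art.article_id,
                "sections": [
                    [s.top_header, s.innermost_header, s.body] for s in art.sections
                ],
                "metadata": art.metadata,
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def read_articles(path: str | Path) -> list[Article]:
    out: list[Article] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                sections = [Section(*triple) for triple in obj["sections"]]
                out.append(
                    Article(
                        article_id=obj["article_id"],
                        sections=sections,
                        metadata=obj.get("metadata", {}),
                    )
                )
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise ValueError(f"{path}: line {lineno}: malformed article: {exc}") from None
    return out
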