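"""Deterministic generator of labeled fixture corpora.

Generated corpora emulate the structure of an annotated RCT limitation
corpus: sectioned articles (Abstract/Introduction/Methods/Results/
Discussion/Study Limitations) whose abstract and discussion/limitation
sections contain template-generated SAL sentences with known labels, at
about 4.8 SAL sentences per article, about 1.15 labels per sentence, and
a long-tailed label distribution in which a handful of types dominate
and several types stay below the augmentation target in a training
split.  Cue phrases are unique per type, so the corpus is separable by a
bag-of-words model — the property smoke tests rely on; real prose is
not imitated.

Of the default label distribution, five frequencies are corpus-reported
statistics (Population 192/1090, OutcomeMeasures 190, UnderpoweredStudy
185, Setting 12, Funding 4); the remaining ten types split the residual
mass with Intervention largest, and are interpolated, not reported
values.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .agreement import UnitLabelMatrix
from .corpus_io import (
    Article,
    LabeledSentence,
    Section,
    SentenceRecord,
    SpanAnnotation,
    flatten_article,
)
from .taxonomy import Taxonomy, load_taxonomy
from .templates import CUE_PHRASES, FILLER_SENTENCES, FINE_FOR_TOP, SAL_SKELETONS

__all__ = [
    "DEFAULT_LABEL_DISTRIBUTION",
    "SynthConfig",
    "SyntheticCorpus",
    "generate_corpus",
    "write_brat",
    "make_multiannotator",
]

# counts per 1090 type instances; starred values are corpus-reported
_LABEL_COUNTS = {
    "Population": 192,          # reported
    "OutcomeMeasures": 190,     # reported
    "UnderpoweredStudy": 185,   # reported
    "Intervention": 120,        # interpolated
    "Generalization": 60,       # interpolated
    "Blinding": 55,             # interpolated
    "StudyDuration": 50,        # interpolated
    "MissingData": 45,          # interpolated
    "StatisticalAnalysis": 40,  # interpolated
    "StudyDesign": 40,          # interpolated
    "Randomization": 35,        # interpolated
    "Other": 32,                # interpolated
    "Control": 30,              # interpolated
    "Setting": 12,              # reported
    "Funding": 4,               # reported
}
_TOTAL = sum(_LABEL_COUNTS.values())

#: Default per-type target frequencies (sum to 1).
DEFAULT_LABEL_DISTRIBUTION = {k: v / _TOTAL for k, v in _LABEL_COUNTS.items()}


@dataclass
class SynthConfig:
    n_articles: int = 200
    label_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_DISTRIBUTION)
    )
    sal_sentences_per_article: float = 4.8
    labels_per_sentence: float = 1.15
    minority_classes: frozenset[str] = frozenset({"Setting", "Funding", "Control", "Other"})
    minority_cap: int = 40  # per-corpus ceiling for minority classes
    fine_label_rate: float = 0.5  # fraction of labels expressed at sub-category level
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_articles < 1:
            raise ValueError("n_articles must be >= 1")
        if any(v < 0 for v in self.label_distribution.values()):
            raise ValueError("label frequencies must be non-negative")
        if self.sal_sentences_per_article < 1 or self.labels_per_sentence < 1:
            raise ValueError("per-article and per-sentence means must be >= 1")
        if self.labels_per_sentence > len(self.label_distribution):
            raise ValueError("labels_per_sentence exceeds the number of types")


@dataclass
class SyntheticCorpus:
    articles: list[Article]
    sentences: list[LabeledSentence]       # section-frame gold records
    spans_by_article: dict[str, list[SpanAnnotation]]  # document-frame spans
    config: SynthConfig

    def gold_for_article(self, article_id: str) -> list[LabeledSentence]:
        return [s for s in self.sentences if s.article_id == article_id]


_SECTION_PLAN = [
    ("Abstract", ""),
    ("Introduction", ""),
    ("Methods", ""),
    ("Results", ""),
    ("Discussion", ""),
    ("Discussion", "Study Limitations"),
]
# indices of sections that may hold SAL sentences (abstract + keyword-matching)
_SAL_SECTIONS = (0, 4, 5)


def _draw_label(rng: random.Random, cfg: SynthConfig, counts: dict[str, int],
                exclude: set[str] | None = None) -> str:
    labels = list(cfg.label_distribution)
    weights = [cfg.label_distribution[l] for l in labels]
    for _ in range(100):
        label = rng.choices(labels, weights=weights, k=1)[0]
        if exclude and label in exclude:
            continue
        if label in cfg.minority_classes and counts.get(label, 0) >= cfg.minority_cap:
            continue
        return label
    # fall back to the most frequent non-excluded label
    for l in sorted(labels, key=lambda x: -cfg.label_distribution[x]):
        if not exclude or l not in exclude:
            return l
    raise RuntimeError("label space exhausted")


def _sal_sentence(rng: random.Random, label: str) -> str:
    cue = rng.choice(CUE_PHRASES[label])
    skeleton = rng.choice(SAL_SKELETONS)
    return skeleton.format(cue=cue)


def generate_corpus(config: SynthConfig | None = None, taxonomy: Taxonomy | None = None) -> SyntheticCorpus:
    """Build a corpus of sectioned articles with gold sentence labels.

    SAL sentences live only in the abstract and keyword-matching sections;
    a sentence gets a second label with probability
    ``labels_per_sentence - 1`` by concatenating two cue templates.
    Byte-identical output for a fixed (config, seed).
    """
    cfg = config or SynthConfig()
    tax = taxonomy or load_taxonomy()
    rng = random.Random(cfg.seed)
    multi_rate = cfg.labels_per_sentence - 1.0
    label_counts: dict[str, int] = {}
    articles: list[Article] = []
    gold: list[LabeledSentence] = []
    spans_by_article: dict[str, list[SpanAnnotation]] = {}

    for a in range(cfg.n_articles):
        art_id = f"SYN{a:04d}"
        # metadata mirrors the journal strata of annotated corpora
        metadata = {
            "journal_type": "general" if rng.random() < 0.26 else "specialty",
            "impact_tier": "high" if rng.random() < 0.33 else "lower",
        }
        n_sal = max(1, _poisson(rng, cfg.sal_sentences_per_article))
        # distribute SAL sentences over the eligible sections
        sal_alloc = {i: 0 for i in _SAL_SECTIONS}
        for _ in range(n_sal):
            sal_alloc[rng.choice(_SAL_SECTIONS)] += 1

        # plan sentences per section: (text, fine_labels or empty)
        section_sentences: dict[int, list[tuple[str, frozenset[str]]]] = {}
        for si, (top_h, inner_h) in enumerate(_SECTION_PLAN):
            sents: list[tuple[str, frozenset[str]]] = []
            n_filler = rng.randint(2, 4)
            for _ in range(n_filler):
                sents.append((rng.choice(FILLER_SENTENCES), frozenset()))
            for _ in range(sal_alloc.get(si, 0)):
                top1 = _draw_label(rng, cfg, label_counts)
                label_counts[top1] = label_counts.get(top1, 0) + 1
                text = _sal_sentence(rng, top1)
                fine1 = _as_fine(rng, cfg, top1)
                fines = {fine1}
                if rng.random() < multi_rate:
                    # a second cue clause makes the sentence multi-label
                    top2 = _draw_label(rng, cfg, label_counts, exclude={top1})
                    label_counts[top2] = label_counts.get(top2, 0) + 1
                    cue2 = rng.choice(CUE_PHRASES[top2])
                    text = text.rstrip(".") + f", and the {cue2} also played a role."
                    fines.add(_as_fine(rng, cfg, top2))
                pos = rng.randrange(len(sents) + 1)
                sents.insert(pos, (text, frozenset(fines)))
            section_sentences[si] = sents

        # materialize section bodies and gold records with offsets
        sections: list[Section] = []
        art_gold: list[LabeledSentence] = []
        for si, (top_h, inner_h) in enumerate(_SECTION_PLAN):
            body_parts: list[str] = []
            pos = 0
            recs: list[tuple[int, int, str, frozenset[str]]] = []
            for text, fines in section_sentences[si]:
                if body_parts:
                    body_parts.append(" ")
                    pos += 1
                recs.append((pos, pos + len(text), text, fines))
                body_parts.append(text)
                pos += len(text)
            body = "".join(body_parts)
            sections.append(Section(top_header=top_h, innermost_header=inner_h, body=body))
            for s, e, text, fines in recs:
                art_gold.append(
                    LabeledSentence(
                        article_id=art_id,
                        section_index=si,
                        char_start=s,
                        char_end=e,
                        text=text,
                        top_header=top_h,
                        innermost_header=inner_h,
                        is_sal=bool(fines),
                        types_fine=frozenset(fines),
                        types_top=tax.coarsen(fines),
                    )
                )
        article = Article(article_id=art_id, sections=sections, metadata=metadata)
        articles.append(article)
        gold.extend(art_gold)
        spans_by_article[art_id] = _spans_for_article(article, art_gold)

    return SyntheticCorpus(
        articles=articles, sentences=gold, spans_by_article=spans_by_article, config=cfg
    )


def _as_fine(rng: random.Random, cfg: SynthConfig, top: str) -> str:
    """Express a top-level label at sub-category level part of the time."""
    fine = FINE_FOR_TOP.get(top, "")
    if fine and rng.random() < cfg.fine_label_rate:
        return fine
    return top


def _poisson(rng: random.Random, lam: float) -> int:
    # Knuth's method; lam is small here
    import math

    L = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= L:
            return k
        k += 1


def _spans_for_article(
    article: Article, gold: list[LabeledSentence]
) -> list[SpanAnnotation]:
    """Document-frame spans: one per (sentence, fine label), over the
    sentence text (span annotations in practice cover variable extents;
    whole-sentence spans keep the projection identity exact)."""
    _, body_offsets = flatten_article(article)
    spans: list[SpanAnnotation] = []
    for rec in gold:
        if not rec.is_sal:
            continue
        off = body_offsets[rec.section_index]
        for label in sorted(rec.types_fine):
            spans.append(
                SpanAnnotation(
                    article_id=article.article_id,
                    char_start=rec.char_start + off,
                    char_end=rec.char_end + off,
                    category=label,
                    annotator_id="gold",
                )
            )
    return spans


def write_brat(corpus: SyntheticCorpus, directory: str | Path) -> list[tuple[Path, Path]]:
    """Write one ``.txt``/``.ann`` pair per article (0-based end-exclusive
    offsets over the flattened article text).  Round-trips through
    ``parse_brat`` + ``project_spans_to_sentences`` to the gold labels."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pairs: list[tuple[Path, Path]] = []
    for art in corpus.articles:
        text, _ = flatten_article(art)
        txt_path = directory / f"{art.article_id}.txt"
        ann_path = directory / f"{art.article_id}.ann"
        txt_path.write_text(text, encoding="utf-8")
        lines = []
        for i, sp in enumerate(corpus.spans_by_article[art.article_id], start=1):
            surface = text[sp.char_start:sp.char_end]
            lines.append(f"T{i}\t{sp.category} {sp.char_start} {sp.char_end}\t{surface}")
        ann_path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
        pairs.append((txt_path, ann_path))
    return pairs


def make_multiannotator(
    corpus: SyntheticCorpus,
    n_annotators: int = 3,
    noise_rate: float = 0.2,
    seed: int = 0,
    granularity: str = "top",
    taxonomy: Taxonomy | None = None,
) -> UnitLabelMatrix:
    """Simulated multi-annotator label matrix over the gold SAL sentences.

    Annotator 1 reproduces the gold labels; each further annotator
    perturbs each unit's set with probability ``noise_rate`` by adding,
    removing, or swapping one label.  Deterministic under ``seed``.
    """
    if not 0.0 <= noise_rate <= 1.0:
        raise ValueError("noise_rate must be in [0, 1]")
    tax = taxonomy or load_taxonomy()
    rng = random.Random(seed)
    space = tax.label_space(granularity)
    units = []
    cells: dict[tuple, frozenset[str]] = {}
    annotators = [f"ann{i+1}" for i in range(n_annotators)]
    for rec in corpus.sentences:
        if not rec.is_sal:
            continue
        unit = (rec.article_id, rec.section_index, rec.char_start)
        gold = rec.types_top if granularity == "top" else rec.types_fine
        units.append(unit)
        cells[(unit, annotators[0])] = gold
        for ann in annotators[1:]:
            labels = set(gold)
            if rng.random() < noise_rate:
                op = rng.choice(("add", "remove", "swap"))
                extra = [l for l in space if l not in labels]
                if op == "add" and extra:
                    labels.add(rng.choice(extra))
                elif op == "remove" and len(labels) > 1:
                    labels.remove(rng.choice(sorted(labels)))
                elif extra and labels:
                    labels.remove(rng.choice(sorted(labels)))
                    labels.add(rng.choice(extra))
            cells[(unit, ann)] = frozenset(labels)
    return UnitLabelMatrix(units=units, annotators=annotators, cells=cells)
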