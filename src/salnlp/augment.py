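"""Class-balancing training-set augmentation.

Minority classes (fewer than 70 training sentences by default) are
brought up to the target size by one of several augmentation routes:
random duplication (oversampling), rule-based sentence perturbation
(EDA: synonym replacement, random insertion/deletion/swap), or
prompt-based dual-view generation — synthesizing candidates conditioned
either on a seed sentence's RAKE keywords (Input View) or on the class
label alone (Output View), followed by optional consistency filtering
that keeps only candidates whose predicted label matches the intended
one.

Eligibility rules: multi-label sentences are excluded from seed pools
(their per-label features are entangled), and the Funding class is never
augmented — it is handled by the rule-based detector instead.  No
augmentation path ever alters, relabels, or removes an original record.

The production sentence generator (a soft-prompt-tuned encoder–decoder)
sits behind :class:`GeneratorContract`; the bundled
:class:`TemplateGenerator` is a deterministic stand-in built from
label-specific sentence skeletons, so every downstream stage runs
offline.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Protocol, Sequence, runtime_checkable

from .corpus_io import LabeledSentence
from .taxonomy import Taxonomy
from .templates import CUE_PHRASES, SAL_SKELETONS
from .textproc import tokenize

__all__ = [
    "DEFAULT_TARGET",
    "DEFAULT_N_PER_SEED",
    "AugmentationPlan",
    "ClassPlan",
    "SyntheticSample",
    "GeneratorContract",
    "GeneratorContractError",
    "TemplateGenerator",
    "build_plan",
    "oversample",
    "eda_variants",
    "rake_keywords",
    "generate_dual_view",
    "consistency_filter",
    "balance",
    "synthetic_to_sentence",
    "DEFAULT_SYNONYMS",
]

#: Minimum class size after augmentation.
DEFAULT_TARGET = 70
#: Candidates generated per seed sentence.
DEFAULT_N_PER_SEED = 10


@dataclass(frozen=True)
class SyntheticSample:
    text: str
    intended_label: str
    view: str  # input_view | output_view | eda | oversample
    seed_sentence_id: str | None = None
    kept_by_filter: bool | None = None


@dataclass
class ClassPlan:
    label: str
    n: int
    deficit: int
    eligible: bool
    seed_ids: list[int] = field(default_factory=list)  # indices into train
    empty_seed_pool: bool = False


@dataclass
class AugmentationPlan:
    target: int
    granularity: str
    classes: dict[str, ClassPlan]

    def deficient(self) -> list[ClassPlan]:
        return [c for c in self.classes.values() if c.eligible and c.deficit > 0]


def _labels_of(rec: LabeledSentence, granularity: str) -> frozenset[str]:
    return rec.types_top if granularity == "top" else rec.types_fine


def build_plan(
    train: Sequence[LabeledSentence],
    target: int = DEFAULT_TARGET,
    granularity: str = "top",
    ineligible: Sequence[str] = ("Funding",),
) -> AugmentationPlan:
    """Per-class counts, deficits and seed pools on the training split.

    Class count n is the number of training sentences carrying the label;
    seeds are the single-label sentences only.  Classes in ``ineligible``
    (Funding by default) are never augmented.
    """
    if target < 1:
        raise ValueError("target must be >= 1")
    sal = [r for r in train if r.is_sal]
    if not sal:
        raise ValueError("training set has no SAL sentences")
    classes: dict[str, ClassPlan] = {}
    for i, rec in enumerate(train):
        labels = _labels_of(rec, granularity)
        for label in labels:
            cp = classes.setdefault(label, ClassPlan(label=label, n=0, deficit=0, eligible=True))
            cp.n += 1
            if len(labels) == 1:
                cp.seed_ids.append(i)
    for cp in classes.values():
        cp.deficit = max(0, target - cp.n)
        cp.eligible = cp.label not in ineligible
        cp.empty_seed_pool = cp.deficit > 0 and cp.eligible and not cp.seed_ids
    return AugmentationPlan(target=target, granularity=granularity, classes=classes)


def oversample(
    train: Sequence[LabeledSentence],
    plan: AugmentationPlan,
    seed: int = 0,
) -> list[LabeledSentence]:
    """Duplicate single-label minority examples until each eligible class
    reaches the target; originals untouched.  A deficient class with an
    empty seed pool is skipped (recorded on the plan)."""
    rng = random.Random(seed)
    out = list(train)
    for cp in sorted(plan.deficient(), key=lambda c: c.label):
        if not cp.seed_ids:
            continue
        for _ in range(cp.deficit):
            out.append(train[rng.choice(cp.seed_ids)])
    return out


# ---------------------------------------------------------------------------
# EDA
# ---------------------------------------------------------------------------

#: Small bundled synonym lexicon; callers may supply their own mapping.
DEFAULT_SYNONYMS: dict[str, list[str]] = {
    "small": ["limited", "modest"],
    "study": ["trial", "investigation"],
    "sample": ["cohort", "group"],
    "short": ["brief", "limited"],
    "results": ["findings", "outcomes"],
    "limitation": ["weakness", "shortcoming"],
    "participants": ["subjects", "patients"],
    "affected": ["influenced", "impacted"],
    "trial": ["study", "experiment"],
    "power": ["sensitivity"],
    "bias": ["distortion"],
    "may": ["might", "could"],
}

_EDA_OPS = ("synonym", "insert", "delete", "swap")


def eda_variants(
    sentence: str,
    label: str,
    n_variants: int = 1,
    rate: float = 0.1,
    seed: int = 0,
    synonym_lexicon: Mapping[str, Sequence[str]] = DEFAULT_SYNONYMS,
    seed_sentence_id: str | None = None,
) -> list[SyntheticSample]:
    """Rule-based perturbations of one sentence, label preserved.

    Each variant applies one randomly chosen operator at the per-word
    ``rate``.  Deletion always retains at least one word; a one-word
    sentence subjected to deletion is returned unchanged.  Deterministic
    under ``seed``.
    """
    if not sentence.strip():
        raise ValueError("empty sentence")
    rng = random.Random(seed)
    words = sentence.split()
    out: list[SyntheticSample] = []
    for _ in range(n_variants):
        op = rng.choice(_EDA_OPS)
        new = _apply_eda(words, op, rate, rng, synonym_lexicon)
        out.append(
            SyntheticSample(
                text=" ".join(new),
                intended_label=label,
                view="eda",
                seed_sentence_id=seed_sentence_id,
            )
        )
    return out


def _strip_word(w: str) -> str:
    return re.sub(r"\W+", "", w).lower()


def _apply_eda(
    words: list[str],
    op: str,
    rate: float,
    rng: random.Random,
    lexicon: Mapping[str, Sequence[str]],
) -> list[str]:
    words = list(words)
    n = len(words)
    n_changes = max(1, round(rate * n))
    if op == "synonym":
        candidates = [i for i, w in enumerate(words) if _strip_word(w) in lexicon]
        rng.shuffle(candidates)
        for i in candidates[:n_changes]:
            words[i] = rng.choice(list(lexicon[_strip_word(words[i])]))
        return words
    if op == "insert":
        pool = [w for w in words if _strip_word(w) in lexicon]
        for _ in range(n_changes):
            if not pool:
                break
            syn = rng.choice(list(lexicon[_strip_word(rng.choice(pool))]))
            words.insert(rng.randrange(len(words) + 1), syn)
        return words
    if op == "delete":
        if n == 1:
            return words
        kept = [w for w in words if rng.random() >= rate]
        if not kept:
            kept = [words[rng.randrange(n)]]
        return kept
    if op == "swap":
        for _ in range(n_changes):
            if len(words) < 2:
                break
            i, j = rng.sample(range(len(words)), 2)
            words[i], words[j] = words[j], words[i]
        return words
    raise ValueError(f"unknown EDA operator {op!r}")


# ---------------------------------------------------------------------------
# RAKE keyword extraction
# ---------------------------------------------------------------------------

def _default_stopwords() -> frozenset[str]:
    from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

    return frozenset(ENGLISH_STOP_WORDS)


def rake_keywords(
    text: str, stopwords: frozenset[str] | set[str] | None = None
) -> list[tuple[str, float]]:
    """Rapid Automatic Keyword Extraction with degree/frequency scoring.

    Candidate phrases are maximal runs of non-stopword tokens between
    stopwords and punctuation.  Each word scores degree/frequency over the
    co-occurrence graph of candidates (degree counts the word itself); a
    phrase scores the sum of its member word scores.  Output is sorted by
    descending score, ties broken by first occurrence.
    """
    if stopwords is None:
        stopwords = _default_stopwords()
    # split on punctuation first, then stopwords delimit candidates
    phrases: list[list[str]] = []
    for fragment in re.split(r"[^\w\s'-]+", text):
        current: list[str] = []
        for tok in tokenize(fragment):
            if tok in stopwords:
                if current:
                    phrases.append(current)
                current = []
            else:
                current.append(tok)
        if current:
            phrases.append(current)
    if not phrases:
        return []
    freq: dict[str, int] = {}
    degree: dict[str, int] = {}
    for ph in phrases:
        for w in ph:
            freq[w] = freq.get(w, 0) + 1
            degree[w] = degree.get(w, 0) + len(ph)
    word_score = {w: degree[w] / freq[w] for w in freq}
    seen: dict[str, tuple[float, int]] = {}
    for pos, ph in enumerate(phrases):
        key = " ".join(ph)
        if key not in seen:
            seen[key] = (sum(word_score[w] for w in ph), pos)
    ranked = sorted(seen.items(), key=lambda kv: (-kv[1][0], kv[1][1]))
    return [(phrase, score) for phrase, (score, _) in ranked]


# ---------------------------------------------------------------------------
# Dual-view generation
# ---------------------------------------------------------------------------

class GeneratorContractError(RuntimeError):
    pass


@runtime_checkable
class GeneratorContract(Protocol):
    """Maps a prompt (keyword list for Input View, label name for Output
    View) and a count to exactly that many non-empty candidate sentences;
    deterministic under its construction seed."""

    def __call__(self, prompt: str | Sequence[str], count: int) -> list[str]:  # pragma: no cover
        ...


class TemplateGenerator:
    """Deterministic template stand-in for the prompt-based generator.

    Output-View prompts (a label name) are filled with that label's cue
    phrases; Input-View prompts (keyword phrases) are spliced directly
    into the skeletons.  Candidates cycle through skeleton/cue
    combinations with a seeded shuffle, so a fixed seed reproduces them.
    """

    def __init__(self, seed: int = 0, cue_phrases: Mapping[str, Sequence[str]] | None = None):
        self._rng = random.Random(seed)
        self._cues = dict(cue_phrases) if cue_phrases is not None else dict(CUE_PHRASES)

    def __call__(self, prompt: str | Sequence[str], count: int) -> list[str]:
        if isinstance(prompt, str):  # Output View: the label name
            fills = list(self._cues.get(prompt, [prompt.lower()]))
        else:  # Input View: keyword phrases from the seed sentence
            fills = [p for p in prompt if p] or ["the reported issue"]
        combos = [(s, f) for f in fills for s in SAL_SKELETONS]
        self._rng.shuffle(combos)
        out = []
        for i in range(count):
            skeleton, fill = combos[i % len(combos)]
            text = skeleton.format(cue=fill)
            if i >= len(combos):  # disambiguate repeats deterministically
                text += f" (variant {i // len(combos)})"
            out.append(text)
        return out


def _sentence_id(rec: LabeledSentence) -> str:
    return f"{rec.article_id}:{rec.section_index}:{rec.char_start}"


def generate_dual_view(
    seed_sample: LabeledSentence,
    generator: GeneratorContract,
    n_per_seed: int = DEFAULT_N_PER_SEED,
    view: str = "output_view",
    granularity: str = "top",
    stopwords: frozenset[str] | None = None,
) -> list[SyntheticSample]:
    """Exactly ``n_per_seed`` candidates for one single-label seed.

    Input View conditions the generator on the seed's RAKE keywords;
    Output View on the label name alone.
    """
    labels = _labels_of(seed_sample, granularity)
    if len(labels) != 1:
        raise ValueError("seed sample must be single-label")
    (label,) = labels
    if view == "input_view":
        keywords = [p for p, _ in rake_keywords(seed_sample.text, stopwords)[:5]]
        prompt: str | Sequence[str] = keywords
    elif view == "output_view":
        prompt = label
    else:
        raise ValueError(f"bad view {view!r}")
    candidates = generator(prompt, n_per_seed)
    if len(candidates) != n_per_seed or any(not c for c in candidates):
        raise GeneratorContractError(
            f"generator returned {len(candidates)} candidates for request of {n_per_seed}"
        )
    sid = _sentence_id(seed_sample)
    return [
        SyntheticSample(text=c, intended_label=label, view=view, seed_sentence_id=sid)
        for c in candidates
    ]


def consistency_filter(
    candidates: Sequence[SyntheticSample],
    filter_model: Callable[[str], str],
) -> list[SyntheticSample]:
    """Keep candidates whose predicted label equals the intended label.

    Returns the kept samples; every input sample's ``kept_by_filter``
    status is recorded on the returned (kept) and discarded copies are
    not mutated (samples are immutable)."""
    kept: list[SyntheticSample] = []
    for cand in candidates:
        ok = filter_model(cand.text) == cand.intended_label
        if ok:
            kept.append(replace(cand, kept_by_filter=True))
    return kept


def balance(
    train: Sequence[LabeledSentence],
    plan: AugmentationPlan,
    pool: Sequence[SyntheticSample],
    seed: int = 0,
) -> tuple[list[LabeledSentence], list[str]]:
    """Fill each deficient eligible class with synthetic samples.

    Exactly ``deficit`` samples are drawn uniformly without replacement
    from the class's pool; a smaller pool contributes in full with a
    shortfall warning.  Returns (augmented training set, warnings);
    deterministic under ``seed``.
    """
    rng = random.Random(seed)
    out = list(train)
    warnings: list[str] = []
    by_label: dict[str, list[SyntheticSample]] = {}
    for s in pool:
        by_label.setdefault(s.intended_label, []).append(s)
    for cp in sorted(plan.deficient(), key=lambda c: c.label):
        avail = list(by_label.get(cp.label, []))
        take = min(cp.deficit, len(avail))
        if take < cp.deficit:
            warnings.append(
                f"class {cp.label!r}: pool of {len(avail)} covers only {take} of "
                f"deficit {cp.deficit}"
            )
        chosen = rng.sample(avail, take) if take else []
        for s in chosen:
            out.append(synthetic_to_sentence(s, plan.granularity))
    return out, warnings


def synthetic_to_sentence(
    sample: SyntheticSample, granularity: str, taxonomy: Taxonomy | None = None
) -> LabeledSentence:
    """Wrap a synthetic sample as a training record.

    At top granularity the fine set mirrors the top set (the sample's
    label is a valid label at both granularities when it is top-level).
    """
    label = frozenset({sample.intended_label})
    if granularity == "top":
        top, fine = label, label
    else:
        fine = label
        top = taxonomy.coarsen(label) if taxonomy is not None else label
    return LabeledSentence(
        article_id=f"synthetic:{sample.view}",
        section_index=0,
        char_start=0,
        char_end=len(sample.text),
        text=sample.text,
        top_header="Discussion",
        innermost_header="Limitations",
        is_sal=True,
        types_fine=fine,
        types_top=top,
    )
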