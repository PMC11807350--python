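"""Multi-label evaluation, paired significance tests, and corpus-level
SAL profiling.

Micro scores pool true/false positives over every (sentence, label)
decision; macro scores average per-label scores.  McNemar's test compares
two classifiers' paired binary correctness via the discordant counts b
and c (chi-square (b-c)^2/(b+c) without continuity correction, switching
to the exact two-sided binomial when b + c < 25).  The Bhapkar test of
marginal homogeneity generalizes McNemar to k categories: with d the
first k-1 marginal differences n_i. - n_.i and S their consistent
covariance estimate (no symmetry assumption), the statistic d'S^-1 d is
chi-square with k-1 degrees of freedom.  Multi-label predictions are
mapped to composite classes via their sorted label tuple before
tabulation; an empty prediction maps to a reserved empty-set class.

Corpus profiling runs the two-stage pipeline (SAL sentence detection,
then type prediction) over abstract and discussion/limitation-related
sections and reports per-type sentence- and document-level counts, plus
per-article means with t-based 95% confidence intervals.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus_io import Article, extract_sentences, select_limitation_sections
from .sentence_model import BinaryClassifier, predict_sal
from .taxonomy import Taxonomy
from .type_model import ThresholdVector, TypeClassifier, predict_with_rules

__all__ = [
    "micro_prf",
    "macro_prf",
    "MacroScores",
    "McNemarResult",
    "mcnemar_test",
    "BhapkarResult",
    "bhapkar_test",
    "encode_labelset",
    "RunSummary",
    "aggregate_runs",
    "CorpusProfile",
    "profile_corpus",
]

EMPTY_CLASS = "∅"  # reserved class for an empty prediction set


def micro_prf(
    gold: Sequence[frozenset[str] | set[str]],
    pred: Sequence[frozenset[str] | set[str]],
) -> tuple[float, float, float]:
    """Micro precision/recall/F1 pooled over (sentence, label) decisions."""
    if len(gold) != len(pred):
        raise ValueError("gold/pred length mismatch")
    tp = fp = fn = 0
    for g, p in zip(gold, pred):
        g, p = set(g), set(p)
        tp += len(g & p)
        fp += len(p - g)
        fn += len(g - p)
    if tp + fn == 0:
        raise ValueError("no gold labels present")
    if tp + fp == 0:
        _warnings.warn("no predicted labels; micro precision reported as 0")
        return 0.0, 0.0, 0.0
    prec = tp / (tp + fp)
    rec = tp / (tp + fn)
    f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
    return prec, rec, f1


@dataclass(frozen=True)
class MacroScores:
    per_label: pd.DataFrame  # columns precision, recall, f1
    precision: float
    recall: float
    f1: float
    excluded_labels: tuple[str, ...] = ()


def macro_prf(
    gold: Sequence[frozenset[str] | set[str]],
    pred: Sequence[frozenset[str] | set[str]],
    label_space: Sequence[str] | None = None,
) -> MacroScores:
    """Unweighted mean of per-label P/R/F1.

    Labels absent from both gold and predictions are excluded from the
    average and reported in ``excluded_labels``.
    """
    if label_space is None:
        label_space = sorted({l for s in gold for l in s} | {l for s in pred for l in s})
    rows, excluded = {}, []
    for label in label_space:
        g = np.array([label in s for s in gold])
        p = np.array([label in s for s in pred])
        if not g.any() and not p.any():
            excluded.append(label)
            continue
        tp = int((g & p).sum()); fp = int((~g & p).sum()); fn = int((g & ~p).sum())
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        rows[label] = (prec, rec, f1)
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=["precision", "recall", "f1"])
    if frame.empty:
        raise ValueError("no labels present in gold or predictions")
    return MacroScores(
        per_label=frame,
        precision=float(frame["precision"].mean()),
        recall=float(frame["recall"].mean()),
        f1=float(frame["f1"].mean()),
        excluded_labels=tuple(excluded),
    )


@dataclass(frozen=True)
class McNemarResult:
    statistic: float
    p_value: float
    b: int
    c: int
    exact: bool


def mcnemar_test(
    correct_a: Sequence[bool],
    correct_b: Sequence[bool],
    exact_below: int = 25,
) -> McNemarResult:
    """Paired test on the discordant counts of two classifiers.

    b = items A got right and B wrong; c = the reverse.  Chi-square
    statistic (b-c)^2/(b+c) against chi2(1); exact two-sided binomial when
    b + c < ``exact_below``.  b + c = 0 yields statistic 0, p = 1.
    """
    if len(correct_a) != len(correct_b):
        raise ValueError("paired outcome length mismatch")
    a = np.asarray(correct_a, dtype=bool)
    bb = np.asarray(correct_b, dtype=bool)
    b = int((a & ~bb).sum())
    c = int((~a & bb).sum())
    n_disc = b + c
    if n_disc == 0:
        return McNemarResult(0.0, 1.0, b, c, exact=False)
    if n_disc < exact_below:
        p = min(1.0, 2.0 * stats.binom.cdf(min(b, c), n_disc, 0.5))
        return McNemarResult(float(min(b, c)), float(p), b, c, exact=True)
    statistic = (b - c) ** 2 / n_disc
    p = float(stats.chi2.sf(statistic, df=1))
    return McNemarResult(float(statistic), p, b, c, exact=False)


def encode_labelset(labels: frozenset[str] | set[str]) -> str:
    """Canonical composite class for a multi-label prediction set."""
    return "+".join(sorted(labels)) if labels else EMPTY_CLASS


@dataclass(frozen=True)
class BhapkarResult:
    statistic: float
    df: int
    p_value: float
    categories: tuple[str, ...]
    singular: bool = False


def bhapkar_test(
    outcomes_a: Sequence[str],
    outcomes_b: Sequence[str],
) -> BhapkarResult:
    """Bhapkar chi-square test of marginal homogeneity for paired
    categorical outcomes.

    Categories are the union of both systems' outcomes.  With a singular
    covariance estimate the Moore-Penrose inverse is used and the degrees
    of freedom reduce to the matrix rank (flagged on the result).
    """
    if len(outcomes_a) != len(outcomes_b) or not outcomes_a:
        raise ValueError("outcomes must be non-empty and aligned")
    cats = sorted(set(outcomes_a) | set(outcomes_b))
    k = len(cats)
    if k < 2:
        raise ValueError("need at least 2 categories")
    idx = {c: i for i, c in enumerate(cats)}
    N = np.zeros((k, k))
    for x, y in zip(outcomes_a, outcomes_b):
        N[idx[x], idx[y]] += 1
    n = N.sum()
    row, col = N.sum(axis=1), N.sum(axis=0)
    d = (row - col)[: k - 1]
    S = np.empty((k - 1, k - 1))
    for i in range(k - 1):
        for j in range(k - 1):
            if i == j:
                S[i, j] = row[i] + col[i] - 2 * N[i, i] - d[i] ** 2 / n
            else:
                S[i, j] = -(N[i, j] + N[j, i]) - d[i] * d[j] / n
    singular = False
    try:
        sol = np.linalg.solve(S, d)
        df = k - 1
    except np.linalg.LinAlgError:
        singular = True
        sol = np.linalg.pinv(S) @ d
        df = int(np.linalg.matrix_rank(S))
        _warnings.warn("singular Bhapkar covariance; generalized inverse used")
    statistic = float(d @ sol)
    if df == 0 or statistic <= 0:
        return BhapkarResult(max(statistic, 0.0), max(df, 1), 1.0, tuple(cats), singular)
    p = float(stats.chi2.sf(statistic, df=df))
    return BhapkarResult(statistic, df, p, tuple(cats), singular)


@dataclass(frozen=True)
class RunSummary:
    mean: float
    sd: float | None
    k: int


def aggregate_runs(values: Sequence[float]) -> RunSummary:
    """Mean and sample SD (k-1 denominator) over repeated runs; SD is
    undefined (None) for a single run."""
    if not values:
        raise ValueError("no run values")
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) >= 2 else None
    return RunSummary(mean=float(arr.mean()), sd=sd, k=len(arr))


def _mean_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    m = float(values.mean())
    if len(values) < 2 or values.std(ddof=1) == 0:
        return m, m, m
    sem = values.std(ddof=1) / np.sqrt(len(values))
    t = stats.t.ppf(0.5 + level / 2, df=len(values) - 1)
    return m, m - t * sem, m + t * sem


@dataclass
class CorpusProfile:
    n_articles: int
    n_sentences_screened: int
    n_sal_sentences: int
    n_articles_with_sal: int
    per_article: pd.DataFrame  # article_id, n_sal, n_types
    type_table: pd.DataFrame   # per type: sentence/document counts and percentages
    sal_sentences_per_article: tuple[float, float, float] = (0.0, 0.0, 0.0)
    types_per_article: tuple[float, float, float] = (0.0, 0.0, 0.0)
    article_types: dict[str, frozenset[str]] = field(default_factory=dict)


def profile_corpus(
    articles: Sequence[Article],
    sentence_model: BinaryClassifier,
    type_model: TypeClassifier,
    thresholds: ThresholdVector,
    taxonomy: Taxonomy,
    *,
    use_funding_rule: bool = True,
    fallback: str = "argmax",
) -> CorpusProfile:
    """Two-stage SAL profile of a corpus.

    Sentences from the abstract and keyword-selected sections are screened
    by the sentence classifier; positives receive type predictions, which
    are coarsened to top level for tabulation.  Document-level counts
    count a type once per article; per-article means carry t-based 95%
    confidence intervals.
    """
    if not articles:
        raise ValueError("empty corpus")
    from .type_model import predict_types  # local to keep import surface flat

    rows = []
    article_types: dict[str, frozenset[str]] = {}
    sent_type_counts: dict[str, int] = {}
    doc_type_counts: dict[str, int] = {}
    n_screened = n_sal_total = 0
    for art in articles:
        secs = select_limitation_sections(art)
        records = extract_sentences(art, secs)
        n_screened += len(records)
        flags = predict_sal(sentence_model, records)
        sal_records = [r for r, (_, pos) in zip(records, flags) if pos]
        n_sal_total += len(sal_records)
        if sal_records:
            if use_funding_rule:
                preds = predict_with_rules(type_model, thresholds, sal_records, fallback=fallback)
            else:
                preds = predict_types(type_model, thresholds, sal_records, fallback=fallback)
            preds = [taxonomy.coarsen(p) for p in preds]
        else:
            preds = []
        doc_types: set[str] = set()
        n_type_instances = 0
        for p in preds:
            n_type_instances += len(p)
            doc_types |= set(p)
            for t in p:
                sent_type_counts[t] = sent_type_counts.get(t, 0) + 1
        for t in doc_types:
            doc_type_counts[t] = doc_type_counts.get(t, 0) + 1
        article_types[art.article_id] = frozenset(doc_types)
        rows.append(
            {"article_id": art.article_id, "n_sal": len(sal_records), "n_types": n_type_instances}
        )
    per_article = pd.DataFrame(rows)
    total_type_instances = sum(sent_type_counts.values())
    table_rows = []
    for t in taxonomy.top_names():
        sc = sent_type_counts.get(t, 0)
        dc = doc_type_counts.get(t, 0)
        table_rows.append(
            {
                "type": t,
                "sentence_count": sc,
                "sentence_pct": 100.0 * sc / total_type_instances if total_type_instances else 0.0,
                "document_count": dc,
                "document_pct": 100.0 * dc / len(articles),
            }
        )
    type_table = pd.DataFrame(table_rows).set_index("type")
    return CorpusProfile(
        n_articles=len(articles),
        n_sentences_screened=n_screened,
        n_sal_sentences=n_sal_total,
        n_articles_with_sal=int((per_article["n_sal"] > 0).sum()),
        per_article=per_article,
        type_table=type_table,
        sal_sentences_per_article=_mean_ci(per_article["n_sal"].to_numpy(dtype=float)),
        types_per_article=_mean_ci(per_article["n_types"].to_numpy(dtype=float)),
        article_types=article_types,
    )
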