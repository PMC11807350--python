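"""Multi-label SAL type classifier with per-label dynamic thresholding.

Only SAL sentences enter training.  The head is a one-hidden-layer MLP
whose softmax output is a probability distribution over the label space;
multi-label gold sets become uniform target distributions over the gold
labels for the cross-entropy objective.  A sigmoid + binary cross-entropy
head is available behind ``head="sigmoid"`` for per-label independent
probabilities.

Dynamic thresholding picks, for each label independently, the grid point
maximizing that label's binary F1 on the development set (ties go to the
smallest threshold).  A label may also be forced by the rule-based
Funding detector, which fires when any stemmed token equals a configured
stem ("financ"/"fund" under the bundled suffix-stripping stemmer; the
literal strings "finance"/"fund" are honored via configuration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .corpus_io import LabeledSentence, SentenceRecord
from .encoders import Encoder, get_encoder
from .sentence_model import TrainConfig, build_input
from .taxonomy import Taxonomy
from .textproc import porter_stem, tokenize

__all__ = [
    "TypeClassifier",
    "ThresholdVector",
    "DEFAULT_GRID",
    "train_type",
    "fit_thresholds",
    "predict_types",
    "funding_rule",
    "predict_with_rules",
]

#: Candidate decision thresholds, 0.01..0.99 step 0.01.
DEFAULT_GRID = tuple(np.round(np.arange(0.01, 1.00, 0.01), 2))

DEFAULT_FUNDING_STEMS = ("financ", "fund")


@dataclass
class TypeClassifier:
    encoder: Encoder
    label_space: list[str]
    granularity: str
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    head: str = "softmax"  # or "sigmoid"
    header_order: str = "headers_first"
    loss_history: list[float] = field(default_factory=list, repr=False)

    def _forward(self, X: np.ndarray) -> np.ndarray:
        h = np.tanh(X @ self.W1 + self.b1)
        z = h @ self.W2 + self.b2
        if self.head == "softmax":
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            return e / e.sum(axis=1, keepdims=True)
        return 1.0 / (1.0 + np.exp(-z))

    def predict_proba(self, records: Sequence[SentenceRecord]) -> np.ndarray:
        """(n, |labels|) label probabilities; softmax rows sum to 1."""
        if not records:
            return np.zeros((0, len(self.label_space)))
        texts = [build_input(r, self.header_order) for r in records]
        return self._forward(self.encoder.encode(texts))


@dataclass
class ThresholdVector:
    thresholds: dict[str, float]
    grid: tuple[float, ...] = DEFAULT_GRID
    warnings: list[str] = field(default_factory=list)

    def as_array(self, label_space: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.thresholds[l] for l in label_space])
        except KeyError as exc:
            raise ValueError(f"threshold missing for label {exc}") from None


def _gold_sets(rec: LabeledSentence, granularity: str) -> frozenset[str]:
    return rec.types_top if granularity == "top" else rec.types_fine


def train_type(
    data: Sequence[LabeledSentence],
    granularity: str,
    config: TrainConfig | None = None,
    *,
    taxonomy: Taxonomy,
    encoder: Encoder | None = None,
    hidden: int = 64,
    head: str = "softmax",
) -> TypeClassifier:
    """Train the MLP head; every sentence must carry >=1 gold label."""
    config = config or TrainConfig(header_order="headers_first")
    if not data:
        raise ValueError("empty training data")
    labels = taxonomy.label_space(granularity)
    index = {name: i for i, name in enumerate(labels)}
    Y = np.zeros((len(data), len(labels)))
    for row, rec in enumerate(data):
        gold = _gold_sets(rec, granularity)
        if not gold:
            raise ValueError(
                f"sentence {rec.article_id}:{rec.char_start} has an empty gold set; "
                "only SAL sentences may enter type training"
            )
        for name in gold:
            if name not in index:
                raise ValueError(f"unknown label {name!r} at granularity {granularity!r}")
            Y[row, index[name]] = 1.0
    if head == "softmax":
        # uniform target distribution over the gold labels
        Y = Y / Y.sum(axis=1, keepdims=True)

    encoder = encoder or get_encoder(config.encoder_name)
    X = encoder.encode([build_input(r, config.header_order) for r in data])
    n, d = X.shape
    k = len(labels)
    rng = np.random.default_rng(config.seed)
    W1 = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, hidden))
    b1 = np.zeros(hidden)
    W2 = rng.normal(0.0, 1.0 / np.sqrt(hidden), size=(hidden, k))
    b2 = np.zeros(k)
    clf = TypeClassifier(
        encoder=encoder, label_space=labels, granularity=granularity,
        W1=W1, b1=b1, W2=W2, b2=b2, head=head, header_order=config.header_order,
    )
    history: list[float] = []
    lr = config.learning_rate
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            Xb, Yb = X[idx], Y[idx]
            h = np.tanh(Xb @ clf.W1 + clf.b1)
            z = h @ clf.W2 + clf.b2
            if head == "softmax":
                z = z - z.max(axis=1, keepdims=True)
                e = np.exp(z)
                P = e / e.sum(axis=1, keepdims=True)
            else:
                P = 1.0 / (1.0 + np.exp(-z))
            dz = (P - Yb) / len(idx)
            gW2 = h.T @ dz + config.l2 * clf.W2
            gb2 = dz.sum(axis=0)
            dh = dz @ clf.W2.T * (1.0 - h * h)
            gW1 = Xb.T @ dh + config.l2 * clf.W1
            gb1 = dh.sum(axis=0)
            clf.W2 -= lr * gW2
            clf.b2 -= lr * gb2
            clf.W1 -= lr * gW1
            clf.b1 -= lr * gb1
        P_all = np.clip(clf._forward(X), 1e-12, 1.0)
        if head == "softmax":
            loss = float(-(Y * np.log(P_all)).sum(axis=1).mean())
        else:
            loss = float(
                -(Y * np.log(P_all) + (1 - Y) * np.log(np.clip(1 - P_all, 1e-12, 1.0))).mean()
            )
        history.append(loss)
    clf.loss_history = history
    return clf


def _binary_f1(gold: np.ndarray, pred: np.ndarray) -> float:
    tp = int((gold & pred).sum())
    fp = int((~gold & pred).sum())
    fn = int((gold & ~pred).sum())
    if 2 * tp + fp + fn == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)


def fit_thresholds(
    probabilities: np.ndarray,
    gold: Sequence[frozenset[str] | set[str]],
    label_space: Sequence[str],
    grid: Sequence[float] = DEFAULT_GRID,
) -> ThresholdVector:
    """Per label, the grid threshold maximizing dev F1 (smallest on ties).

    A label never appearing in the dev gold gets the grid maximum and a
    warning, since no threshold is estimable for it.
    """
    if len(probabilities) == 0 or len(gold) != len(probabilities):
        raise ValueError("dev probabilities and gold sets must be non-empty and aligned")
    grid = list(grid)
    if not grid or any(not (0 < t < 1) for t in grid) or sorted(grid) != grid:
        raise ValueError("grid must be strictly increasing within (0, 1)")
    thresholds: dict[str, float] = {}
    warnings: list[str] = []
    for j, label in enumerate(label_space):
        g = np.array([label in s for s in gold])
        if not g.any():
            thresholds[label] = float(grid[-1])
            warnings.append(f"label {label!r} absent from dev gold; threshold set to grid max")
            continue
        p = probabilities[:, j]
        best_t, best_f1 = grid[0], -1.0
        for t in grid:
            f1 = _binary_f1(g, p >= t)
            if f1 > best_f1:
                best_t, best_f1 = t, f1
        thresholds[label] = float(best_t)
    return ThresholdVector(thresholds=thresholds, grid=tuple(grid), warnings=warnings)


def predict_types(
    model: TypeClassifier,
    thresholds: ThresholdVector,
    records: Sequence[SentenceRecord],
    fallback: str = "argmax",
) -> list[frozenset[str]]:
    """Labels whose probability meets their threshold; optional argmax
    fallback when nothing qualifies (all inputs are SAL sentences, so an
    empty type set is implausible)."""
    if fallback not in ("argmax", "empty"):
        raise ValueError(f"bad fallback {fallback!r}")
    if set(thresholds.thresholds) != set(model.label_space):
        raise ValueError("threshold vector and model label space differ")
    P = model.predict_proba(records)
    tvec = thresholds.as_array(model.label_space)
    out: list[frozenset[str]] = []
    for row in P:
        picked = {model.label_space[j] for j in np.nonzero(row >= tvec)[0]}
        if not picked and fallback == "argmax":
            picked = {model.label_space[int(row.argmax())]}
        out.append(frozenset(picked))
    return out


def funding_rule(
    sentence: str,
    stemmer: Callable[[str], str] = porter_stem,
    stems: Sequence[str] = DEFAULT_FUNDING_STEMS,
) -> bool:
    """True iff any token's stem equals a configured funding stem."""
    targets = set(stems)
    return any(stemmer(tok) in targets for tok in tokenize(sentence))


def predict_with_rules(
    model: TypeClassifier,
    thresholds: ThresholdVector,
    records: Sequence[SentenceRecord],
    fallback: str = "argmax",
    stems: Sequence[str] = DEFAULT_FUNDING_STEMS,
) -> list[frozenset[str]]:
    """Classifier predictions unioned with {Funding} where the rule fires."""
    preds = predict_types(model, thresholds, records, fallback=fallback)
    out = []
    for rec, labels in zip(records, preds):
        if funding_rule(rec.text, stems=stems):
            labels = labels | {"Funding"}
        out.append(frozenset(labels))
    return out
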