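"""Binary SAL sentence classifier.

The input representation concatenates the target sentence with its two
section headers (top and innermost) around a separator marker; the header
order is configurable because the binary task traditionally places the
sentence first while the type task prepends the headers.  A linear head
over the pooled encoder representation produces a single logit trained
under binary cross-entropy; the decision threshold defaults to 0.5 and
``probability >= threshold`` is positive.

Training is plain mini-batch gradient descent in numpy with seeded
initialization and data order, so fixed (seed, config, data) reproduce
predictions bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus_io import LabeledSentence, SentenceRecord
from .encoders import SEP, Encoder, get_encoder

__all__ = [
    "TrainConfig",
    "BinaryClassifier",
    "BinaryScores",
    "build_input",
    "train_binary",
    "predict_sal",
    "evaluate_binary",
]


@dataclass
class TrainConfig:
    """Optimization settings; defaults are repository choices sized for the
    bundled encoder, not published values."""

    epochs: int = 60
    learning_rate: float = 0.5
    batch_size: int = 32
    seed: int = 0
    max_length: int = 256
    encoder_name: str = "hashing"
    header_order: str = "sentence_first"  # or "headers_first"
    l2: float = 1e-4

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.max_length) <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs, learning_rate, batch_size, max_length must be positive")
        if self.header_order not in ("sentence_first", "headers_first"):
            raise ValueError(f"bad header_order {self.header_order!r}")


def build_input(record: SentenceRecord, order: str = "sentence_first", sep: str = SEP) -> str:
    """Join sentence and headers with the separator marker.

    ``sentence_first``: sentence, top header, innermost header.
    ``headers_first``: top header, innermost header, sentence.
    Empty headers keep their slots (separators retained).
    """
    if order == "sentence_first":
        parts = (record.text, record.top_header, record.innermost_header)
    elif order == "headers_first":
        parts = (record.top_header, record.innermost_header, record.text)
    else:
        raise ValueError(f"bad order {order!r}")
    return sep.join(parts)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class BinaryClassifier:
    encoder: Encoder
    weights: np.ndarray
    bias: float
    decision_threshold: float = 0.5
    header_order: str = "sentence_first"
    loss_history: list[float] = field(default_factory=list, repr=False)

    def predict_proba(self, records: Sequence[SentenceRecord]) -> np.ndarray:
        if not records:
            return np.zeros(0)
        texts = [build_input(r, self.header_order) for r in records]
        feats = self.encoder.encode(texts)
        return _sigmoid(feats @ self.weights + self.bias)


def train_binary(
    data: Sequence[LabeledSentence],
    config: TrainConfig | None = None,
    encoder: Encoder | None = None,
) -> BinaryClassifier:
    """Train the linear head under binary cross-entropy.

    Requires both classes present; raises ``ValueError`` otherwise.
    """
    config = config or TrainConfig()
    if not data:
        raise ValueError("empty training data")
    y = np.array([1.0 if r.is_sal else 0.0 for r in data])
    if y.min() == y.max():
        raise ValueError("training data contains a single class; need both")
    encoder = encoder or get_encoder(config.encoder_name)
    texts = [build_input(r, config.header_order) for r in data]
    X = encoder.encode(texts)
    n, d = X.shape
    rng = np.random.default_rng(config.seed)
    w = rng.normal(0.0, 0.01, size=d)
    b = 0.0
    history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            p = _sigmoid(X[idx] @ w + b)
            err = p - y[idx]
            gw = X[idx].T @ err / len(idx) + config.l2 * w
            gb = float(err.mean())
            w -= config.learning_rate * gw
            b -= config.learning_rate * gb
        p_all = np.clip(_sigmoid(X @ w + b), 1e-12, 1 - 1e-12)
        bce = float(-(y * np.log(p_all) + (1 - y) * np.log(1 - p_all)).mean())
        history.append(bce)
    return BinaryClassifier(
        encoder=encoder,
        weights=w,
        bias=b,
        header_order=config.header_order,
        loss_history=history,
    )


def predict_sal(
    model: BinaryClassifier, records: Sequence[SentenceRecord]
) -> list[tuple[float, bool]]:
    """Per record: (probability, probability >= decision_threshold)."""
    probs = model.predict_proba(records)
    t = model.decision_threshold
    return [(float(p), bool(p >= t)) for p in probs]


@dataclass(frozen=True)
class BinaryScores:
    precision: float
    recall: float
    f1: float
    accuracy: float
    no_predicted_positives: bool = False


def evaluate_binary(gold: Sequence[bool], pred: Sequence[bool]) -> BinaryScores:
    """Positive-class precision/recall/F1 plus accuracy.

    With no predicted positives, precision (and hence F1) is reported as 0
    and flagged rather than raising.
    """
    if len(gold) != len(pred):
        raise ValueError("gold/pred length mismatch")
    g = np.asarray(gold, dtype=bool)
    p = np.asarray(pred, dtype=bool)
    tp = int((g & p).sum())
    fp = int((~g & p).sum())
    fn = int((g & ~p).sum())
    no_pos = (tp + fp) == 0
    prec = 0.0 if no_pos else tp / (tp + fp)
    rec = 0.0 if (tp + fn) == 0 else tp / (tp + fn)
    f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
    acc = float((g == p).mean()) if len(g) else 0.0
    return BinaryScores(prec, rec, f1, acc, no_predicted_positives=no_pos)
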