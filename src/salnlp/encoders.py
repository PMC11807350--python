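"""Pluggable text-encoder contract and the bundled deterministic encoder.

An encoder maps a batch of input strings to a fixed-width pooled
representation (one vector per input).  Classification heads are trained
on top of this representation.  Any object exposing ``dim`` and
``encode(texts) -> (n, dim) float64 array`` satisfies the contract, so a
transformer pooled-output encoder can be dropped in; the bundled default
is a signed feature-hashing encoder over word uni- and bigrams, which is
fully deterministic across processes and platforms (token indices come
from a cryptographic digest, not the process hash seed).
"""

from __future__ import annotations

import hashlib
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .textproc import tokenize

__all__ = ["Encoder", "HashingEncoder", "SEP", "get_encoder"]

#: Separator marker used when concatenating a sentence with its headers.
SEP = " [SEP] "


@runtime_checkable
class Encoder(Protocol):
    dim: int
    name: str

    def encode(self, texts: Sequence[str]) -> np.ndarray:  # pragma: no cover
        ...


def _hash_index(token: str, dim: int) -> tuple[int, float]:
    h = hashlib.md5(token.encode("utf-8")).digest()
    idx = int.from_bytes(h[:4], "little") % dim
    sign = 1.0 if h[4] & 1 else -1.0
    return idx, sign


class HashingEncoder:
    """Signed feature hashing of word uni- and bigrams, L2-normalized."""

    def __init__(self, dim: int = 512, use_bigrams: bool = True) -> None:
        self.dim = dim
        self.use_bigrams = use_bigrams
        self.name = f"hashing-{dim}"

    def encode(self, texts: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(texts), self.dim), dtype=np.float64)
        for row, text in enumerate(texts):
            toks = tokenize(text)
            feats = list(toks)
            if self.use_bigrams:
                feats.extend(f"{a}_{b}" for a, b in zip(toks, toks[1:]))
            for f in feats:
                idx, sign = _hash_index(f, self.dim)
                out[row, idx] += sign
            norm = np.linalg.norm(out[row])
            if norm > 0:
                out[row] /= norm
        return out


def get_encoder(name: str = "hashing", dim: int = 512) -> Encoder:
    """Resolve an encoder by name. Only the bundled family is registered
    here; callers may pass their own :class:`Encoder` objects anywhere an
    encoder is accepted."""
    if name.startswith("hashing"):
        if "-" in name:
            dim = int(name.split("-", 1)[1])
        return HashingEncoder(dim=dim)
    raise ValueError(f"unknown encoder {name!r}; pass an Encoder instance instead")
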