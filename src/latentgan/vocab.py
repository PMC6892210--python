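"""SMILES tokenization and one-hot encoding.

Tokenization is token-level rather than character-level: two-character
halogens (``Cl``, ``Br``) and bracketed atom expressions (``[nH]``, ``[O-]``)
are single tokens, so that joining the tokens always reproduces the string and
a decoder can never emit half a halogen.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

# Bracket atoms first, then two-char halogens, ring-bond ten-plus (%nn),
# then any single character.
_TOKEN_RE = re.compile(r"(\[[^\]]+\]|Cl|Br|%\d{2}|.)")

START, END, PAD = "^", "$", " "


class TokenizationError(ValueError):
    pass


class UnknownTokenError(TokenizationError):
    pass


class TooLongError(TokenizationError):
    pass


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into tokens; joining them reproduces the input."""
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:  # pragma: no cover - regex is total
        raise TokenizationError(f"lossy tokenization of {smiles!r}")
    return tokens


@dataclass
class Vocabulary:
    """Token inventory with reserved start/end/pad tokens and a length cap.

    ``max_length`` covers start + tokens + end; sequences are padded to it.
    Index 0 is always the pad token so zero-padding is consistent.
    """

    tokens: list[str]
    max_length: int
    start_token: str = START
    end_token: str = END
    pad_token: str = PAD
    index_of: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        reserved = [self.pad_token, self.start_token, self.end_token]
        if len(set(reserved)) != 3:
            raise ValueError("reserved tokens must be distinct")
        ordered = reserved + [t for t in self.tokens if t not in reserved]
        if len(set(ordered)) != len(ordered):
            raise ValueError("duplicate tokens")
        self.tokens = ordered
        self.index_of = {t: i for i, t in enumerate(ordered)}

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_index(self) -> int:
        return self.index_of[self.pad_token]

    @property
    def start_index(self) -> int:
        return self.index_of[self.start_token]

    @property
    def end_index(self) -> int:
        return self.index_of[self.end_token]

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "tokens": self.tokens,
                "max_length": self.max_length,
                "start_token": self.start_token,
                "end_token": self.end_token,
                "pad_token": self.pad_token,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        d = json.loads(text)
        return cls(
            tokens=d["tokens"],
            max_length=d["max_length"],
            start_token=d["start_token"],
            end_token=d["end_token"],
            pad_token=d["pad_token"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        return cls.from_json(Path(path).read_text())


def build_vocabulary(corpus: Iterable[str], length_margin: int = 0) -> Vocabulary:
    """Collect every token occurring in the corpus; max_length is the longest
    tokenized entry + 2 (start and end) plus an optional margin.

    The margin gives headroom for randomized renderings of corpus molecules,
    which can tokenize slightly longer than any string in the sweep.
    """
    seen: dict[str, None] = {}
    longest = 0
    n = 0
    for smiles in corpus:
        toks = tokenize(smiles)
        longest = max(longest, len(toks))
        for t in toks:
            seen.setdefault(t, None)
        n += 1
    if n == 0:
        raise ValueError("empty corpus")
    return Vocabulary(tokens=list(seen), max_length=longest + 2 + length_margin)


def encode_indices(smiles: str, vocab: Vocabulary) -> np.ndarray:
    """start + tokens + end, padded with pad_index to ``vocab.max_length``."""
    toks = tokenize(smiles)
    if len(toks) + 2 > vocab.max_length:
        raise TooLongError(f"{smiles!r} exceeds max_length {vocab.max_length}")
    idx = [vocab.start_index]
    for t in toks:
        if t not in vocab.index_of:
            raise UnknownTokenError(f"token {t!r} not in vocabulary")
        idx.append(vocab.index_of[t])
    idx.append(vocab.end_index)
    idx.extend([vocab.pad_index] * (vocab.max_length - len(idx)))
    return np.asarray(idx, dtype=np.int64)


def encode_one_hot(smiles: str, vocab: Vocabulary) -> np.ndarray:
    """One-hot matrix of shape (max_length, len(vocab)); exactly one 1 per row."""
    idx = encode_indices(smiles, vocab)
    out = np.zeros((vocab.max_length, len(vocab)), dtype=np.float64)
    out[np.arange(vocab.max_length), idx] = 1.0
    return out


def decode_indices(indices: Sequence[int], vocab: Vocabulary) -> str:
    """Inverse of :func:`encode_indices`: strip start, stop at end/pad, join."""
    toks = []
    for i in indices:
        t = vocab.tokens[int(i)]
        if t == vocab.start_token:
            continue
        if t in (vocab.end_token, vocab.pad_token):
            break
        toks.append(t)
    return "".join(toks)


def encode_batch(smiles_batch: Sequence[str], vocab: Vocabulary) -> tuple[np.ndarray, np.ndarray]:
    """Index matrix (B, max_length) and true lengths (start..end inclusive)."""
    mat = np.stack([encode_indices(s, vocab) for s in smiles_batch])
    lengths = np.array([len(tokenize(s)) + 2 for s in smiles_batch], dtype=np.int64)
    return mat, lengths
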