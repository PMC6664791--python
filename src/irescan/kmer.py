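"""Global and windowed local kmer frequency features.

Frequencies are counts (overlapping occurrences) divided by the length of
the counted region: the whole sequence for global features, the window's
actual length for local features. With k running 1..4 this yields
4 + 16 + 64 + 256 = 340 global features; a 173-base sequence with 20-base
windows stepping 10 gives 16 full windows (5440 local features) or 17
windows including the truncated final one (5780 features, last start 161).

Positions containing non-ACGU characters contribute no counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError
from .sequence_io import RNA_ALPHABET, RnaSequence

BASES = "ACGU"  # lexicographic A < C < G < U


@dataclass(frozen=True)
class KmerSpace:
    """The ordered vocabulary of kmer words for k in [min_k, max_k]."""

    min_k: int = 1
    max_k: int = 4

    def __post_init__(self):
        if self.min_k < 1:
            raise ValueError("min_k must be >= 1")
        if self.max_k > 8:
            raise ValueError("max_k must be <= 8")
        if self.min_k > self.max_k:
            raise ValueError("min_k must be <= max_k")

    def words(self) -> list[str]:
        return enumerate_kmers(self)

    @property
    def size(self) -> int:
        return sum(4**k for k in range(self.min_k, self.max_k + 1))


@dataclass(frozen=True)
class LocalWindowConfig:
    """Windowing rule for local kmers: fixed-length windows from the 5' end.

    Window starts are the 1-based positions 1, 1+step, 1+2*step, ...
    ``partial_final_window`` appends one trailing truncated window when the
    sequence does not divide evenly (its length must still fit max_k).
    """

    window: int = 20
    step: int = 10
    partial_final_window: bool = False

    def __post_init__(self):
        if not (0 < self.step <= self.window):
            raise ValueError("require 0 < step <= window")

    def starts(self, seq_len: int, min_len: int = 1) -> list[tuple[int, int]]:
        """1-based (start, end) pairs of windows over a sequence."""
        out = []
        start = 1
        while start + self.window - 1 <= seq_len:
            out.append((start, start + self.window - 1))
            start += self.step
        if self.partial_final_window and start <= seq_len:
            if seq_len - start + 1 >= min_len:
                out.append((start, seq_len))
        return out


@dataclass(frozen=True)
class FeatureVector:
    """Named, ordered real-valued features."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))

    @staticmethod
    def concat(*vectors: "FeatureVector") -> "FeatureVector":
        names = tuple(itertools.chain.from_iterable(v.names for v in vectors))
        values = np.concatenate([v.values for v in vectors])
        return FeatureVector(names, values)


def enumerate_kmers(space: KmerSpace) -> list[str]:
    """All words for each k in the space, k ascending, lexicographic within k."""
    words = []
    for k in range(space.min_k, space.max_k + 1):
        words.extend("".join(p) for p in itertools.product(BASES, repeat=k))
    return words


def _count_words(region: str, space: KmerSpace) -> dict[str, int]:
    counts: dict[str, int] = {}
    n = len(region)
    for k in range(space.min_k, space.max_k + 1):
        for i in range(n - k + 1):
            word = region[i : i + k]
            # skip windows touching ambiguity characters
            if not RNA_ALPHABET.issuperset(word):
                continue
            counts[word] = counts.get(word, 0) + 1
    return counts


def global_kmer_features(
    seq: RnaSequence, space: KmerSpace | None = None
) -> FeatureVector:
    """Kmer frequencies over the whole sequence: count / sequence length."""
    space = space or KmerSpace()
    if seq.length < space.max_k:
        raise DegenerateInputError(
            f"sequence {seq.id!r} shorter than max_k={space.max_k}"
        )
    words = enumerate_kmers(space)
    counts = _count_words(seq.residues, space)
    values = np.array([counts.get(w, 0) for w in words], dtype=float)
    values /= seq.length
    return FeatureVector(tuple(words), values)


def local_kmer_features(
    seq: RnaSequence,
    space: KmerSpace | None = None,
    cfg: LocalWindowConfig | None = None,
) -> FeatureVector:
    """Windowed kmer frequencies; names are ``<word>_<window start>``.

    Each window's counts are divided by that window's actual length.
    """
    space = space or KmerSpace()
    cfg = cfg or LocalWindowConfig()
    windows = cfg.starts(seq.length, min_len=space.max_k)
    if not windows:
        raise DegenerateInputError(
            f"sequence {seq.id!r} (length {seq.length}) holds no "
            f"{cfg.window}-base window"
        )
    words = enumerate_kmers(space)
    names: list[str] = []
    chunks: list[np.ndarray] = []
    for start, end in windows:
        region = seq.residues[start - 1 : end]
        counts = _count_words(region, space)
        vals = np.array([counts.get(w, 0) for w in words], dtype=float)
        vals /= len(region)
        names.extend(f"{w}_{start}" for w in words)
        chunks.append(vals)
    return FeatureVector(tuple(names), np.concatenate(chunks))


def parse_local_name(name: str) -> tuple[str, int]:
    """Invert the ``<word>_<start>`` naming of local features."""
    word, _, start = name.rpartition("_")
    return word, int(start)


def feature_matrix(
    vectors: Sequence[FeatureVector],
) -> tuple[list[str], np.ndarray]:
    """Stack identically-configured vectors into (names, matrix)."""
    if not vectors:
        return [], np.empty((0, 0))
    names = list(vectors[0].names)
    for v in vectors[1:]:
        if list(v.names) != names:
            raise ValueError("feature vectors have differing name lists")
    return names, np.vstack([v.values for v in vectors])
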