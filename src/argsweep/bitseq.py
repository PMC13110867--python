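"""Bit-packed haplotypes and haplotype pseudometrics.

A haplotype over ``s`` biallelic markers is a vector of GF(2): 0 encodes the
wild (ancestral) allele and 1 the derived allele.  Haplotypes are packed
LSB-first into 64-bit machine words (marker 0 is the least significant bit of
word 0) so that the two operations driving mutation detection -- addition
(XOR) and multiplication (AND) on GF(2) -- map onto whole-word bitwise
instructions.  Distances between haplotypes are *pseudo*metrics: two distinct
haplotypes may be at distance zero, which is exactly what permits building
trees consistent with a single marker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence as TySequence

import numpy as np

__all__ = [
    "Sequence",
    "Sample",
    "Metric",
    "hamming_distance",
    "left_distance",
    "biased_distance",
    "masked_xor",
    "interval_mask",
]

_WORD = 64


def _n_words(s: int) -> int:
    return max(1, (s + _WORD - 1) // _WORD)


def _pad_mask(s: int) -> np.ndarray:
    """AND-mask zeroing every bit at index >= s (canonical padding)."""
    nw = _n_words(s)
    m = np.full(nw, ~np.uint64(0), dtype=np.uint64)
    rem = s % _WORD
    if rem:
        m[-1] = np.uint64((1 << rem) - 1)
    if s == 0:
        m[:] = 0
    return m


class Sequence:
    """An immutable bit-packed vector of ``s`` markers over GF(2).

    Bits beyond index ``s`` are kept at zero so that equality and hashing of
    the packed words are meaningful.
    """

    __slots__ = ("words", "s")

    def __init__(self, words: np.ndarray, s: int):
        words = np.asarray(words, dtype=np.uint64)
        if words.shape != (_n_words(s),):
            raise ValueError(f"expected {_n_words(s)} words for s={s}")
        words = words & _pad_mask(s)
        words.setflags(write=False)
        self.words = words
        self.s = s

    # -- constructors -------------------------------------------------
    @classmethod
    def zeros(cls, s: int) -> "Sequence":
        return cls(np.zeros(_n_words(s), dtype=np.uint64), s)

    @classmethod
    def ones(cls, s: int) -> "Sequence":
        return cls(_pad_mask(s).copy(), s)

    @classmethod
    def from_bits(cls, bits: Iterable[int]) -> "Sequence":
        bits = list(bits)
        s = len(bits)
        w = np.zeros(_n_words(s), dtype=np.uint64)
        for k, b in enumerate(bits):
            if b not in (0, 1):
                raise ValueError("bits must be 0 or 1")
            if b:
                w[k // _WORD] |= np.uint64(1 << (k % _WORD))
        return cls(w, s)

    # -- canonical unpack ---------------------------------------------
    def to_bits(self) -> list[int]:
        return [self.bit(k) for k in range(self.s)]

    def bit(self, k: int) -> int:
        if not 0 <= k < self.s:
            raise IndexError(f"marker index {k} out of range [0, {self.s})")
        return int((int(self.words[k // _WORD]) >> (k % _WORD)) & 1)

    # -- GF(2) arithmetic ---------------------------------------------
    def __xor__(self, other: "Sequence") -> "Sequence":
        self._check(other)
        return Sequence(self.words ^ other.words, self.s)

    def __and__(self, other: "Sequence") -> "Sequence":
        self._check(other)
        return Sequence(self.words & other.words, self.s)

    def __or__(self, other: "Sequence") -> "Sequence":
        self._check(other)
        return Sequence(self.words | other.words, self.s)

    def __invert__(self) -> "Sequence":
        return Sequence(~self.words & _pad_mask(self.s), self.s)

    def popcount(self) -> int:
        return int(np.bitwise_count(self.words).sum())

    def is_zero(self) -> bool:
        return not self.words.any()

    def chunk(self, k0: int, k1: int) -> int:
        """Bits ``k0 .. k1-1`` as a Python integer (bit 0 = marker k0)."""
        if not (0 <= k0 <= k1 <= self.s):
            raise IndexError("chunk out of range")
        out = 0
        # Assemble from whole words, then shift.  Chunks are short (<= 64
        # markers) in practice so this loop is at most two iterations.
        w0, w1 = k0 // _WORD, (k1 - 1) // _WORD if k1 > k0 else k0 // _WORD
        acc = 0
        for wi in range(w0, w1 + 1):
            acc |= int(self.words[wi]) << ((wi - w0) * _WORD)
        out = (acc >> (k0 - w0 * _WORD)) & ((1 << (k1 - k0)) - 1)
        return out

    def set_bit_indices(self) -> list[int]:
        """Indices of set bits via trailing-zeros iteration."""
        out: list[int] = []
        for wi, w in enumerate(self.words):
            w = int(w)
            base = wi * _WORD
            while w:
                lsb = w & -w
                out.append(base + lsb.bit_length() - 1)
                w ^= lsb
        return out

    def _check(self, other: "Sequence") -> None:
        if not isinstance(other, Sequence):
            raise TypeError("expected a Sequence")
        if self.s != other.s:
            raise ValueError(f"length mismatch: {self.s} != {other.s}")

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Sequence)
            and self.s == other.s
            and bool(np.array_equal(self.words, other.words))
        )

    def __hash__(self) -> int:
        return hash((self.s, self.words.tobytes()))

    def __repr__(self) -> str:
        shown = "".join(str(self.bit(k)) for k in range(min(self.s, 40)))
        if self.s > 40:
            shown += "..."
        return f"Sequence({shown}, s={self.s})"


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Sample:
    """A sample of ``n`` phased, polarized haplotypes.

    Parameters
    ----------
    sequences:
        The ``n`` haplotypes, all of identical marker count ``s``.
    positions:
        Strictly increasing physical marker positions in bp, all in
        ``[0, seq_length)``.
    seq_length:
        Total sequence length ``l`` in bp.
    mu_prime:
        Per-locus (per-bp, per-generation) diploid mutation rate.
    Ne:
        Diploid effective population size.

    The global mutation rate is ``mu = 4 * Ne * mu_prime * seq_length``.
    """

    sequences: tuple[Sequence, ...]
    positions: np.ndarray
    seq_length: float
    mu_prime: float
    Ne: float

    def __init__(self, sequences, positions, seq_length, mu_prime, Ne):
        sequences = tuple(sequences)
        if len(sequences) < 1:
            raise ValueError("sample must contain at least one sequence")
        s = sequences[0].s
        if any(h.s != s for h in sequences):
            raise ValueError("all sequences must have the same marker count")
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (s,):
            raise ValueError("positions must match the marker count")
        if s and (np.any(np.diff(positions) <= 0)):
            raise ValueError("positions must be strictly increasing")
        if s and (positions[0] < 0 or positions[-1] >= seq_length):
            raise ValueError("positions must lie in [0, seq_length)")
        positions.setflags(write=False)
        object.__setattr__(self, "sequences", sequences)
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "seq_length", float(seq_length))
        object.__setattr__(self, "mu_prime", float(mu_prime))
        object.__setattr__(self, "Ne", float(Ne))

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def s(self) -> int:
        return self.sequences[0].s

    @property
    def mu(self) -> float:
        return 4.0 * self.Ne * self.mu_prime * self.seq_length

    def genotype_matrix(self) -> np.ndarray:
        """(s, n) 0/1 matrix, one column per haplotype."""
        return np.array([h.to_bits() for h in self.sequences], dtype=np.int8).T


# ---------------------------------------------------------------------------
# Pseudometrics


def hamming_distance(a: Sequence, b: Sequence) -> int:
    """Number of markers at which ``a`` and ``b`` differ."""
    a._check(b)
    return (a ^ b).popcount()


def left_distance(a: Sequence, b: Sequence) -> int:
    """0 if the first markers agree, 1 otherwise."""
    if a.s < 1 or b.s < 1:
        raise ValueError("left_distance requires at least one marker")
    a._check(b)
    return a.bit(0) ^ b.bit(0)


@dataclass(frozen=True)
class Metric:
    """A (possibly biased) haplotype pseudometric.

    ``kind`` selects the base distance; ``c0`` rescales it.  ``c0 = 0`` makes
    every pair equidistant (distance 0) while ``c0 = inf`` sends every
    positive distance to infinity, turning the pairing weight into a hard
    0/1 constraint.
    """

    kind: str = "hamming"
    c0: float = 1.0
    fn: object = None  # custom callable for kind == "custom"

    def __post_init__(self):
        if self.kind not in ("hamming", "left", "custom"):
            raise ValueError(f"unknown metric kind {self.kind!r}")
        if self.kind == "custom" and not callable(self.fn):
            raise ValueError("custom metric requires a callable")
        if not (self.c0 >= 0):  # rejects NaN and negatives
            raise ValueError("c0 must be nonnegative (possibly inf)")

    def base(self, a: Sequence, b: Sequence) -> float:
        if self.kind == "hamming":
            return hamming_distance(a, b)
        if self.kind == "left":
            return left_distance(a, b)
        return float(self.fn(a, b))

    def __call__(self, a: Sequence, b: Sequence) -> float:
        return biased_distance(self, a, b)


def biased_distance(m: Metric, a: Sequence, b: Sequence) -> float:
    """``c0 * d(a, b)`` with the convention ``0 * inf = 0``."""
    d = m.base(a, b)
    if d == 0:
        return 0.0
    if m.c0 == 0:
        return 0.0
    if math.isinf(m.c0):
        return math.inf
    return m.c0 * d


# ---------------------------------------------------------------------------
# Masked mutation detection primitives


def masked_xor(parent: Sequence, child: Sequence, mask: Sequence) -> Sequence:
    """``(parent XOR child) AND mask``.

    Set bits mark markers that mutate on the parent-child edge within the
    genomic region encoded by ``mask``.
    """
    parent._check(child)
    parent._check(mask)
    return Sequence((parent.words ^ child.words) & mask.words, parent.s)


def interval_mask(positions: TySequence[float] | np.ndarray, omega) -> Sequence:
    """AND-mask with bit ``k`` set iff ``positions[k]`` lies in ``omega``.

    ``omega`` is an :class:`~argsweep.intervals.IntervalSet`; an empty set
    yields the zero mask.
    """
    positions = np.asarray(positions, dtype=float)
    s = positions.size
    if len(omega) == 0:
        return Sequence.zeros(s)
    bounds = np.asarray(omega.flat_bounds(), dtype=float)
    inside = (np.searchsorted(bounds, positions, side="right") % 2) == 1
    w = np.zeros(_n_words(s), dtype=np.uint64)
    for k in np.nonzero(inside)[0]:
        w[k // _WORD] |= np.uint64(1 << (int(k) % _WORD))
    return Sequence(w, s)
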