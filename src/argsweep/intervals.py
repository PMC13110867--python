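"""Canonical finite unions of half-open genomic intervals.

Ancestral material carried by an edge of an ancestral recombination graph is
a finite union of disjoint half-open intervals ``[a, b)`` in bp, as are the
left/right recombination masks attached to recombination vertices.  All set
algebra here is exact endpoint arithmetic: no tolerance merging is ever
applied, and every operation returns the canonical form (sorted, disjoint,
no empty and no adjacent-mergeable members).  The right endpoint may be
``inf``, which is how masks partition the whole genome ``[0, inf)``.
"""

from __future__ import annotations

import math
from typing import Iterable, Iterator

__all__ = ["IntervalSet", "EMPTY", "genome_mask_pair"]


class IntervalSet:
    """An immutable, canonical union of disjoint half-open intervals."""

    __slots__ = ("_ivs",)

    def __init__(self, intervals: Iterable[tuple[float, float]] = (), *, _canonical=False):
        ivs = [(float(a), float(b)) for a, b in intervals]
        if not _canonical:
            ivs = _canonicalize(ivs)
        else:
            _validate(ivs)
        self._ivs = tuple(ivs)

    # -- basic protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self._ivs)

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return iter(self._ivs)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, IntervalSet) and self._ivs == other._ivs

    def __hash__(self) -> int:
        return hash(self._ivs)

    def __repr__(self) -> str:
        body = " u ".join(f"[{a:g},{b:g})" for a, b in self._ivs) or "{}"
        return f"IntervalSet({body})"

    @property
    def intervals(self) -> tuple[tuple[float, float], ...]:
        return self._ivs

    def is_empty(self) -> bool:
        return not self._ivs

    def flat_bounds(self) -> list[float]:
        out: list[float] = []
        for a, b in self._ivs:
            out.append(a)
            out.append(b)
        return out

    # -- queries --------------------------------------------------------
    def contains(self, p: float) -> bool:
        for a, b in self._ivs:
            if a <= p < b:
                return True
            if p < a:
                return False
        return False

    def measure(self) -> float:
        return sum(b - a for a, b in self._ivs)

    def min(self) -> float:
        if not self._ivs:
            raise ValueError("empty interval set has no minimum")
        return self._ivs[0][0]

    def max(self) -> float:
        if not self._ivs:
            raise ValueError("empty interval set has no maximum")
        return self._ivs[-1][1]

    def closure(self) -> "IntervalSet":
        """The single interval ``[min a, max b)``."""
        if not self._ivs:
            return EMPTY
        return IntervalSet([(self._ivs[0][0], self._ivs[-1][1])], _canonical=True)

    def overlaps_interval(self, a: float, b: float) -> bool:
        """True iff the set intersects ``[a, b]`` (closed query window)."""
        for x, y in self._ivs:
            if x <= b and a < y:
                return True
        return False

    # -- algebra ----------------------------------------------------------
    def union(self, other: "IntervalSet") -> "IntervalSet":
        if self.is_empty():
            return other
        if other.is_empty():
            return self
        return IntervalSet(_canonicalize(list(self._ivs) + list(other._ivs)),
                           _canonical=True)

    def intersection(self, other: "IntervalSet") -> "IntervalSet":
        out = []
        i = j = 0
        a, b = self._ivs, other._ivs
        while i < len(a) and j < len(b):
            lo = max(a[i][0], b[j][0])
            hi = min(a[i][1], b[j][1])
            if lo < hi:
                out.append((lo, hi))
            if a[i][1] <= b[j][1]:
                i += 1
            else:
                j += 1
        return IntervalSet(out, _canonical=True)

    def complement(self) -> "IntervalSet":
        """Complement within the genome ``[0, inf)``."""
        out = []
        prev = 0.0
        for a, b in self._ivs:
            if prev < a:
                out.append((prev, a))
            prev = b
        if not math.isinf(prev):
            out.append((prev, math.inf))
        return IntervalSet(out, _canonical=True)

    def difference(self, other: "IntervalSet") -> "IntervalSet":
        return self.intersection(other.complement())

    def clip(self, lo: float, hi: float) -> "IntervalSet":
        return self.intersection(IntervalSet([(lo, hi)]))

    __or__ = union
    __and__ = intersection
    __sub__ = difference


def _validate(ivs) -> None:
    prev_b = -math.inf
    for a, b in ivs:
        if not a < b:
            raise ValueError(f"empty or inverted interval [{a},{b})")
        if a <= prev_b:
            raise ValueError("intervals not disjoint/sorted or adjacent-mergeable")
        prev_b = b


def _canonicalize(ivs: list[tuple[float, float]]) -> list[tuple[float, float]]:
    for a, b in ivs:
        if math.isnan(a) or math.isnan(b):
            raise ValueError("NaN interval endpoint")
        if not a < b:
            raise ValueError(f"empty or inverted interval [{a},{b})")
    ivs = sorted(ivs)
    out: list[tuple[float, float]] = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            if b > out[-1][1]:
                out[-1] = (out[-1][0], b)
        else:
            out.append((a, b))
    return out


EMPTY = IntervalSet()


def genome_mask_pair(b: float) -> tuple[IntervalSet, IntervalSet]:
    """The initial recombination mask ``{[0, b), [b, inf)}`` for breakpoint b."""
    if not 0 < b < math.inf:
        raise ValueError("breakpoint must be finite and positive")
    return IntervalSet([(0.0, b)]), IntervalSet([(b, math.inf)])
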