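"""Post-event graph maintenance.

After a recombination-and-recoalescence or multiple-crossover event, every
vertex upstream of the modified edges must have its haplotype (AND of its
children's) and its parental edges' ancestral intervals (mask intersected
with the union of the child edges' intervals) recomputed.  Propagation stops
early on any edge whose (haplotype, ancestral interval) pair is unchanged;
to avoid copying state, "unchanged" is decided by comparing 64-bit universal
hashes of the pair (NH family, pairwise collision probability at most
2^-64).  The final :func:`~argsweep.genealogy.validate` pass is the safety
net against the astronomically unlikely collision.

This module also provides the marker position <-> index pseudoinverse used
for masking, an interpolation-sequential search seeded by a least-squares
linear fit of index on position.
"""

from __future__ import annotations

import heapq
import math

import numpy as np

from .genealogy import COAL, Genealogy, RECOMB, StructuralError
from .intervals import IntervalSet

__all__ = ["NHKey", "state_hash", "update_upstream", "PositionIndex"]

_M32 = (1 << 32) - 1
_M64 = (1 << 64) - 1


class NHKey:
    """Lazily extended stream of 32-bit key lanes for the NH hash."""

    def __init__(self, seed: int | None = 0):
        self._rng = np.random.default_rng(seed)
        self._lanes: list[int] = []

    def lanes(self, n: int) -> list[int]:
        while len(self._lanes) < n:
            self._lanes.extend(
                int(x) for x in self._rng.integers(0, 1 << 32, size=64,
                                                   dtype=np.uint64))
        return self._lanes[:n]


def state_hash(haplotype, interval: IntervalSet, key: NHKey) -> int:
    """NH universal hash of a (haplotype, ancestral interval) pair.

    The pair is serialized into 32-bit lanes (packed haplotype words, then
    interval endpoints as raw float bits, then both lengths) and hashed as
    ``sum_i (x_{2i} + k_{2i}) * (x_{2i+1} + k_{2i+1}) mod 2^64`` with
    additions modulo 2^32.
    """
    lanes: list[int] = []
    for w in haplotype.words:
        w = int(w)
        lanes.append(w & _M32)
        lanes.append(w >> 32)
    for a, b in interval:
        for v in (a, b):
            bits = np.float64(v).view(np.uint64)
            bits = int(bits)
            lanes.append(bits & _M32)
            lanes.append(bits >> 32)
    lanes.append(haplotype.s & _M32)
    lanes.append(len(interval) & _M32)
    if len(lanes) % 2:
        lanes.append(0)
    k = key.lanes(len(lanes))
    h = 0
    for i in range(0, len(lanes), 2):
        h = (h + ((lanes[i] + k[i]) & _M32) * ((lanes[i + 1] + k[i + 1]) & _M32)) & _M64
    return h


def update_upstream(g: Genealogy, seeds, *, key: NHKey | None = None,
                    use_hash: bool = True, touch_log: list | None = None) -> None:
    """Propagate haplotype/interval recomputation upward from ``seeds``.

    ``seeds`` is an iterable of edges whose state may have changed; their
    parent vertices are re-evaluated in latitude order (children before
    parents), pushing further parents only through edges whose state hash
    actually changed.  With ``use_hash=False`` the comparison is exact
    equality of the pair instead (used as the oracle in tests).
    """
    if key is None:
        key = getattr(g, "hash_key", None) or NHKey(0)
    heap: list[tuple[float, int]] = []
    pending: set[int] = set()

    def push(v: int) -> None:
        if v not in pending:
            pending.add(v)
            heapq.heappush(heap, (g.latitude[v], v))

    for e in seeds:
        push(e.parent)
    pops = 0
    while heap:
        pops += 1
        if pops > 4 * g.n_vertices + 16:
            raise StructuralError("update_upstream did not settle (cycle?)")
        _, v = heapq.heappop(heap)
        pending.discard(v)
        if touch_log is not None:
            touch_log.append(v)
        if g.kind[v] not in (COAL, RECOMB):
            raise StructuralError(f"leaf {v} cannot be updated")
        new_h = g.recompute_haplotype(v)  # recombination: reference, no copy
        base = g.vertex_ancestral(v)
        old_h = g.haplotype[v]
        g.haplotype[v] = new_h
        for e in g.parent_edges[v]:
            new_anc = g.mask_for_edge(e).intersection(base)
            if use_hash:
                changed = (state_hash(old_h, e.ancestral, key)
                           != state_hash(new_h, new_anc, key))
            else:
                changed = old_h != new_h or e.ancestral != new_anc
            if changed:
                e.ancestral = new_anc
                push(e.parent)


# ---------------------------------------------------------------------------
# Marker positions


class PositionIndex:
    """Pseudoinverse of the marker index -> position map.

    ``pos_to_idx(p) = sup{ i in 1..s : idx_to_pos(i) <= p }`` with the
    convention that an empty supremum (``p`` left of every marker) returns
    the sentinel 0.  Queries are answered by interpolation-sequential
    search: a first guess from a least-squares linear fit of index on
    position, then a short monotone scan.  The fit is computed once; the
    position vector never changes over a genealogy's lifetime.
    """

    def __init__(self, positions, seq_length: float):
        self.positions = np.asarray(positions, dtype=float)
        self.seq_length = float(seq_length)
        self.s = self.positions.size
        if self.s == 0:
            raise ValueError("need at least one marker")
        if self.s >= 2:
            self._slope, self._icept = np.polyfit(
                self.positions, np.arange(1, self.s + 1, dtype=float), 1)
        else:
            self._slope, self._icept = 0.0, 1.0

    def idx_to_pos(self, i: int) -> float:
        """Position of 1-based marker ``i``."""
        if not 1 <= i <= self.s:
            raise IndexError(f"marker index {i} outside [1, {self.s}]")
        return float(self.positions[i - 1])

    def pos_to_idx(self, p: float) -> int:
        if not 0.0 <= p < self.seq_length:
            raise ValueError(f"position {p} outside [0, {self.seq_length})")
        i = int(round(self._slope * p + self._icept))
        i = min(max(i, 1), self.s)
        pos = self.positions
        while i < self.s and pos[i] <= p:  # pos[i] is marker i+1
            i += 1
        while i >= 1 and pos[i - 1] > p:
            i -= 1
        return i
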