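"""Minimum-mutation-number scanning.

Detecting where a genealogy is inconsistent with its sample reduces to GF(2)
arithmetic on packed haplotypes: for an edge ancestral for a region omega,
``(h_parent XOR h_child) AND m_omega`` has a set bit exactly at the markers
that mutate on that edge inside omega.  The scanner walks the markers
left-to-right in fixed-width chunks (8 by default), XOR/ANDing every live
edge's chunk, and reports the first marker at or right of the cursor whose
marginal tree carries two or more mutation edges, together with the set M of
those edges.  Because 0 is absorbing for AND, an edge whose child haplotype
chunk is all zeros can be skipped outright: its parent chunk is all zeros
too (the AND rule), so the XOR cannot have set bits.  Results never depend
on the chunk width or on whether zero chunks are skipped.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .bitseq import interval_mask
from .genealogy import Edge, Genealogy
from .intervals import IntervalSet

__all__ = ["MutationScanResult", "edge_mutations", "next_inconsistent",
           "DEFAULT_CHUNK"]

DEFAULT_CHUNK = 8


@dataclass(frozen=True)
class MutationScanResult:
    """First inconsistent marker (1-based) and its mutation edges."""

    marker_index: int
    marker_position: float
    mutation_edges: tuple[Edge, ...]


def edge_mutations(g: Genealogy, e: Edge, omega: IntervalSet) -> list[int]:
    """0-based indices of markers in ``omega`` mutating on edge ``e``."""
    mask = interval_mask(g.sample.positions, omega)
    x = (g.haplotype[e.parent] ^ g.haplotype[e.child]) & mask
    return x.set_bit_indices()


def _edge_mask(g: Genealogy, e: Edge):
    return g.edge_marker_mask(e)


def next_inconsistent(g: Genealogy, from_marker: int = 1,
                      window: IntervalSet | None = None,
                      chunk: int = DEFAULT_CHUNK,
                      skip_zero_chunks: bool = True) -> MutationScanResult | None:
    """Find the first marker >= ``from_marker`` with >= 2 mutation edges.

    ``from_marker`` is 1-based, as is the reported ``marker_index``.
    ``window`` optionally restricts the scan to markers inside an interval
    set.  Returns ``None`` when every remaining marker is consistent.
    """
    s = g.sample.s
    if not 1 <= from_marker <= s:
        raise ValueError(f"from_marker {from_marker} outside [1, {s}]")
    if chunk < 1:
        raise ValueError("chunk width must be >= 1")
    positions = g.sample.positions
    cursor = from_marker - 1  # 0-based
    start = (cursor // chunk) * chunk
    wmask = None if window is None else interval_mask(positions, window)
    edges = list(g.iter_edges())
    haps = g.haplotype
    for k0 in range(start, s, chunk):
        k1 = min(k0 + chunk, s)
        hits: dict[int, list[Edge]] = defaultdict(list)
        for e in edges:
            hc = haps[e.child]
            cc = hc.chunk(k0, k1)
            if skip_zero_chunks and cc == 0:
                # child chunk all-wild forces the parent chunk all-wild
                continue
            x = haps[e.parent].chunk(k0, k1) ^ cc
            if not x:
                continue
            x &= _edge_mask(g, e).chunk(k0, k1)
            if wmask is not None:
                x &= wmask.chunk(k0, k1)
            while x:
                lsb = x & -x
                hits[k0 + lsb.bit_length() - 1].append(e)
                x ^= lsb
        for k in range(max(k0, cursor), k1):
            if len(hits[k]) >= 2:
                edges_k = tuple(sorted(hits[k], key=lambda e: e.child))
                return MutationScanResult(k + 1, float(positions[k]), edges_k)
    return None
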