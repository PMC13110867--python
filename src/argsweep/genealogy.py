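"""Coalescent trees and ancestral recombination graphs.

A genealogy is a directed acyclic graph over a sample of ``n`` haplotypes.
Leaves sit at latitude 0; every edge points from a child vertex to a parent
vertex of strictly greater latitude (latitudes are in coalescent units of
``2 Ne`` generations).  Coalescence vertices have two children and at most
one parent; recombination vertices have one child and two parents, with a
*recombination mask* -- a partition ``{m_left, m_right}`` of ``[0, inf)`` --
deciding which genomic material flows to which parent.

The load-bearing structural rule is the *interval rule*: the ancestral
interval set of a parental edge equals the intersection of its recombination
mask (``[0, inf)`` for coalescence vertices) with the union of the ancestral
interval sets of the child edges of its child vertex.  Restricting the graph
to edges ancestral for a position ``p`` and contracting degree-2 vertices
yields the *marginal tree* at ``p``, a binary tree over the full sample.

A genealogy is *consistent* with its sample under the infinite-sites model
when every marker has at most one mutation edge (an edge ancestral for the
marker whose endpoint haplotypes differ there) in its marginal tree.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .bitseq import Sample, Sequence
from .intervals import EMPTY, IntervalSet

__all__ = [
    "Edge",
    "RecombinationMask",
    "Genealogy",
    "Tree",
    "Arg",
    "MarginalTree",
    "marginal_tree",
    "is_consistent",
    "validate",
    "stats",
    "GenealogyStats",
    "StructuralError",
]

LEAF = "leaf"
COAL = "coalescence"
RECOMB = "recombination"


class StructuralError(ValueError):
    """A genealogy violates a structural invariant (degrees, latitudes,
    interval rule, mask partition...), as opposed to mere ISM inconsistency."""


@dataclass(frozen=True)
class RecombinationMask:
    left: IntervalSet
    right: IntervalSet

    def side(self, name: str) -> IntervalSet:
        return self.left if name == "left" else self.right


class Edge:
    """A directed child -> parent edge carrying ancestral material."""

    __slots__ = ("id", "child", "parent", "ancestral", "side", "alive",
                 "_mmask")

    def __init__(self, eid: int, child: int, parent: int,
                 ancestral: IntervalSet, side: str | None = None):
        self.id = eid
        self.child = child
        self.parent = parent
        self.ancestral = ancestral
        self.side = side  # 'left'/'right' for parental edges of a recombination
        self.alive = True
        self._mmask = None  # marker-mask cache keyed on the ancestral object

    def length(self, g: "Genealogy") -> float:
        return g.latitude[self.parent] - g.latitude[self.child]

    def __repr__(self) -> str:
        return (f"Edge({self.child}->{self.parent}, {self.ancestral!r}"
                + (f", {self.side}" if self.side else "") + ")")


class Genealogy:
    """Mutable vertex/edge store shared by trees and ARGs."""

    def __init__(self, sample: Sample):
        self.sample = sample
        n = sample.n
        self.latitude: list[float] = [0.0] * n
        self.haplotype: list[Sequence] = list(sample.sequences)
        self.kind: list[str] = [LEAF] * n
        self.child_edges: list[list[Edge]] = [[] for _ in range(n)]
        self.parent_edges: list[list[Edge]] = [[] for _ in range(n)]
        self.masks: dict[int, RecombinationMask] = {}
        self.root: int | None = None
        self.log_density: float = 0.0
        self._edges: list[Edge] = []
        self._n_dead = 0
        # bookkeeping for tree_log_density
        self.density_terms: list[tuple[str, float]] = []

    # -- construction -------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return self.sample.n

    @property
    def n_vertices(self) -> int:
        return len(self.latitude)

    def new_vertex(self, latitude: float, haplotype: Sequence, kind: str) -> int:
        self.latitude.append(float(latitude))
        self.haplotype.append(haplotype)
        self.kind.append(kind)
        self.child_edges.append([])
        self.parent_edges.append([])
        return len(self.latitude) - 1

    def add_edge(self, child: int, parent: int, ancestral: IntervalSet,
                 side: str | None = None) -> Edge:
        if not self.latitude[parent] > self.latitude[child]:
            raise StructuralError(
                f"edge {child}->{parent} would not increase latitude")
        e = Edge(len(self._edges), child, parent, ancestral, side)
        self._edges.append(e)
        self.child_edges[parent].append(e)
        self.parent_edges[child].append(e)
        return e

    def remove_edge(self, e: Edge) -> None:
        if not e.alive:
            raise StructuralError("edge already removed")
        e.alive = False
        self.child_edges[e.parent].remove(e)
        self.parent_edges[e.child].remove(e)
        self._n_dead += 1

    def iter_edges(self):
        for e in self._edges:
            if e.alive:
                yield e

    @property
    def n_edges(self) -> int:
        return len(self._edges) - self._n_dead

    def n_recombinations(self) -> int:
        return sum(1 for k in self.kind if k == RECOMB)

    def is_tree(self) -> bool:
        return self.n_recombinations() == 0

    # -- haplotype semantics -------------------------------------------
    def edge_marker_mask(self, e: Edge) -> Sequence:
        """Marker mask of an edge's ancestral material (cached per edge)."""
        from .bitseq import interval_mask  # local import avoids a cycle
        cached = e._mmask
        if cached is not None and cached[0] is e.ancestral:
            return cached[1]
        m = interval_mask(self.sample.positions, e.ancestral)
        e._mmask = (e.ancestral, m)
        return m

    def recompute_haplotype(self, v: int) -> Sequence:
        """Haplotype implied by ``v``'s children.

        A coalescence vertex carries, at each marker, the AND of the alleles
        of the children whose edges are *ancestral* for that marker;
        children contributing no material there are neutral (a marker nobody
        carries defaults to 1, which is never consulted).  A recombination
        vertex simply references its child's haplotype.
        """
        es = self.child_edges[v]
        if self.kind[v] == RECOMB:
            return self.haplotype[es[0].child]
        e1, e2 = es
        h1 = self.haplotype[e1.child] | ~self.edge_marker_mask(e1)
        h2 = self.haplotype[e2.child] | ~self.edge_marker_mask(e2)
        return h1 & h2

    # -- navigation ----------------------------------------------------
    def vertex_ancestral(self, v: int) -> IntervalSet:
        """Union of ancestral material entering ``v`` from below."""
        if self.kind[v] == LEAF:
            return IntervalSet([(0.0, self.sample.seq_length)])
        out = EMPTY
        for e in self.child_edges[v]:
            out = out | e.ancestral
        return out

    def mask_for_edge(self, e: Edge) -> IntervalSet:
        """Recombination mask side for a parental edge; [0, inf) otherwise."""
        if self.kind[e.child] == RECOMB:
            return self.masks[e.child].side(e.side)
        return IntervalSet([(0.0, math.inf)])

    def parent_edge_at(self, v: int, p: float) -> Edge | None:
        """The parent edge routing position ``p`` upward from ``v``.

        For recombination vertices the routing is decided by the mask, not by
        ancestrality, so it is defined even for non-ancestral material.
        """
        pes = self.parent_edges[v]
        if not pes:
            return None
        if self.kind[v] == RECOMB:
            mask = self.masks[v]
            want = "left" if mask.left.contains(p) else "right"
            for e in pes:
                if e.side == want:
                    return e
            return None
        return pes[0]

    def ancestral_parent_edge_at(self, v: int, p: float) -> Edge | None:
        """The unique parent edge ancestral at ``p``, if any."""
        for e in self.parent_edges[v]:
            if e.ancestral.contains(p):
                return e
        return None

    def is_ancestral_vertex_at(self, v: int, p: float) -> bool:
        """True iff ``v`` carries sample material at position ``p``."""
        if self.kind[v] == LEAF:
            return 0.0 <= p < self.sample.seq_length
        return any(e.ancestral.contains(p) for e in self.child_edges[v])

    def first_ancestral_status(self, v: int, marker: int) -> int:
        """Allele at ``marker`` of the first vertex at or above ``v`` that is
        ancestral for the marker's position (mask-routed walk)."""
        p = float(self.sample.positions[marker])
        u = v
        while u is not None:
            if self.is_ancestral_vertex_at(u, p):
                return self.haplotype[u].bit(marker)
            e = self.parent_edge_at(u, p)
            u = e.parent if e is not None else None
        # No ancestral vertex on the routed path: fall back to the root state.
        return self.haplotype[self.root].bit(marker)

    def mutation_edges_at(self, marker: int) -> list[Edge]:
        """Edges of the marker's marginal tree whose endpoints differ there."""
        p = float(self.sample.positions[marker])
        out = [e for e in self.iter_edges()
               if e.ancestral.contains(p)
               and self.haplotype[e.child].bit(marker)
               != self.haplotype[e.parent].bit(marker)]
        out.sort(key=lambda e: e.child)
        return out

    def mutation_count_at(self, marker: int) -> int:
        return len(self.mutation_edges_at(marker))


class Tree(Genealogy):
    """A full binary coalescent tree on ``n`` leaves."""


class Arg(Genealogy):
    """An ancestral recombination graph."""

    @classmethod
    def from_tree(cls, tree: Tree) -> "Arg":
        g = cls(tree.sample)
        g.latitude = list(tree.latitude)
        g.haplotype = list(tree.haplotype)
        g.kind = list(tree.kind)
        g.child_edges = [[] for _ in range(len(tree.latitude))]
        g.parent_edges = [[] for _ in range(len(tree.latitude))]
        g.root = tree.root
        g.log_density = tree.log_density
        for e in tree.iter_edges():
            g.add_edge(e.child, e.parent, e.ancestral, e.side)
        g.masks = dict(tree.masks)
        return g


# ---------------------------------------------------------------------------
# Marginal trees


@dataclass
class MarginalTree:
    """Contracted binary tree at one genomic position.

    ``parent_of`` maps every marginal vertex except the root to its marginal
    parent (contracting pass-through vertices of the underlying graph).
    """

    position: float
    root: int
    parent_of: dict[int, int]
    latitude: dict[int, float]
    leaves: tuple[int, ...]

    def children_of(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = defaultdict(list)
        for v, u in self.parent_of.items():
            out[u].append(v)
        return out

    def tmrca(self, i: int, j: int) -> float:
        anc_i = {i: 0}
        v = i
        while v in self.parent_of:
            v = self.parent_of[v]
            anc_i[v] = 1
        v = j
        while v not in anc_i:
            v = self.parent_of[v]
        return self.latitude[v]

    def mean_pairwise_tmrca(self) -> float:
        leaves = self.leaves
        n = len(leaves)
        tot = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                tot += self.tmrca(leaves[i], leaves[j])
        return tot / (n * (n - 1) / 2)


def marginal_tree(g: Genealogy, p: float) -> MarginalTree:
    """Extract the marginal tree of ``g`` at position ``p``."""
    if not 0.0 <= p < g.sample.seq_length:
        raise ValueError(f"position {p} outside [0, {g.sample.seq_length})")
    anc_children: dict[int, int] = defaultdict(int)
    for e in g.iter_edges():
        if e.ancestral.contains(p):
            anc_children[e.parent] += 1

    def climb(v: int) -> int | None:
        # first vertex above v where two ancestral lineages meet
        u = v
        while True:
            e = g.ancestral_parent_edge_at(u, p)
            if e is None:
                return None
            u = e.parent
            if anc_children[u] >= 2:
                return u

    parent_of: dict[int, int] = {}
    latitude: dict[int, float] = {}
    leaves = tuple(range(g.n_leaves))
    for leaf in leaves:
        v = leaf
        latitude[v] = g.latitude[v]
        while v not in parent_of:
            u = climb(v)
            if u is None:
                break
            parent_of[v] = u
            latitude[u] = g.latitude[u]
            v = u
    tops = set(latitude) - set(parent_of)
    if len(tops) != 1:
        raise StructuralError(f"marginal tree at {p} has {len(tops)} roots")
    return MarginalTree(p, tops.pop(), parent_of, latitude, leaves)


# ---------------------------------------------------------------------------
# Validation


def validate(g: Genealogy) -> None:
    """Check every structural invariant; raise ``StructuralError`` on failure.

    ISM consistency is *not* checked here -- use :func:`is_consistent` --
    so that structural corruption and mere sample inconsistency are reported
    distinctly.
    """
    n = g.n_leaves
    n_coal = n_rec = 0
    for v in range(g.n_vertices):
        kind = g.kind[v]
        nc, np_ = len(g.child_edges[v]), len(g.parent_edges[v])
        if kind == LEAF:
            if g.latitude[v] != 0.0 or nc != 0:
                raise StructuralError(f"leaf {v} malformed")
        elif kind == COAL:
            n_coal += 1
            if nc != 2 or np_ > 1:
                raise StructuralError(
                    f"coalescence vertex {v} has degree ({nc} children, {np_} parents)")
        elif kind == RECOMB:
            n_rec += 1
            if nc != 1 or np_ != 2:
                raise StructuralError(
                    f"recombination vertex {v} has degree ({nc} children, {np_} parents)")
            mask = g.masks.get(v)
            if mask is None:
                raise StructuralError(f"recombination vertex {v} lacks a mask")
            if mask.left.intersection(mask.right) != EMPTY \
                    or mask.left.union(mask.right) != IntervalSet([(0.0, math.inf)]):
                raise StructuralError(f"mask of {v} does not partition [0, inf)")
            sides = sorted(e.side for e in g.parent_edges[v])
            if sides != ["left", "right"]:
                raise StructuralError(f"parental edges of {v} not labelled left/right")
        else:
            raise StructuralError(f"unknown vertex kind {kind!r}")
    if n_coal != n_rec + n - 1:
        raise StructuralError(
            f"counting invariant violated: {n_coal} coalescences, {n_rec} recombinations")
    roots = [v for v in range(g.n_vertices) if not g.parent_edges[v]]
    if len(roots) != 1 or roots[0] != g.root:
        raise StructuralError(f"expected a unique root {g.root}, found {roots}")
    for e in g.iter_edges():
        if not g.latitude[e.parent] > g.latitude[e.child]:
            raise StructuralError(f"non-increasing latitude along {e!r}")
        expected = g.mask_for_edge(e).intersection(g.vertex_ancestral(e.child))
        if e.ancestral != expected:
            raise StructuralError(
                f"interval rule violated on {e!r}: expected {expected!r}")
    for v in range(n, g.n_vertices):
        if g.haplotype[v] != g.recompute_haplotype(v):
            raise StructuralError(f"haplotype rule violated at vertex {v}")


def is_consistent(g: Genealogy) -> tuple[bool, np.ndarray]:
    """Infinite-sites consistency check.

    Returns ``(ok, counts)`` where ``counts[k]`` is the number of mutation
    edges in marker ``k``'s marginal tree; ``ok`` iff all counts are <= 1.
    """
    counts = np.array([g.mutation_count_at(k) for k in range(g.sample.s)],
                      dtype=int)
    return bool(np.all(counts <= 1)), counts


# ---------------------------------------------------------------------------
# Summary statistics


@dataclass(frozen=True)
class GenealogyStats:
    n_recombinations: int
    tree_height: float
    diversity: float


def stats(g: Genealogy) -> GenealogyStats:
    """Recombination count, gMRCA latitude, and branch diversity.

    Diversity is the average over leaf pairs of twice the pairwise TMRCA,
    integrated uniformly over ``[0, l)`` (position-weighted, not
    marker-weighted).
    """
    l = g.sample.seq_length
    cuts = {0.0, l}
    for e in g.iter_edges():
        for a, b in e.ancestral:
            if 0.0 < a < l:
                cuts.add(a)
            if 0.0 < b < l:
                cuts.add(b)
    cuts = sorted(cuts)
    div = 0.0
    for a, b in zip(cuts[:-1], cuts[1:]):
        mt = marginal_tree(g, (a + b) / 2.0)
        div += (b - a) * 2.0 * mt.mean_pairwise_tmrca()
    return GenealogyStats(
        n_recombinations=g.n_recombinations(),
        tree_height=g.latitude[g.root],
        diversity=div / l,
    )
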