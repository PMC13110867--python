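"""Recombination event generation and the consistency sweep.

An ARG is inferred from an initial coalescent tree by a left-to-right sweep:
find the next marker whose marginal tree carries two or more mutation edges,
then generate *constrained* recombination-and-recoalescence (RR) events --
each guaranteed to strictly reduce that marker's mutation count -- until a
single mutation edge remains, and move on.  Constrained events restrict the
support of the coalescent-with-recombination distributions (edge choice
proportional to branch length, Beta(2,2) locations, unit-rate recoalescence)
only as much as consistency requires.

Two families of constrained events exist.  A *derived* event recombines a
mutation edge (or an edge below it along a chain of marginally siblingless
edges) and recoalesces the freed derived lineage with another derived
lineage, eliminating exactly one mutation.  A *wild* event recombines a wild
edge whose marginal brother and uncle are both mutation edges; the freed
wild lineage recoalesces with a lineage that leads to a wild branch, and the
brother/uncle merger can cascade through "derived cousins", eliminating one
or more mutations.  When the edge drawn for recombination is a parental edge
of an existing recombination vertex, the same effect may be achievable by
editing that vertex's recombination mask instead of adding vertices -- a
multiple-crossover (MCO) event.

Breakpoints live in ``[b_i', m)`` where ``m`` is the focal marker position
and the lower bound ``b_i'`` is pushed left of the previous marker as far as
three per-marker conditions allow (identical alleles on the recombining and
recoalescing lineages; recombination edge non-ancestral; recoalescence edge
non-ancestral with a matching first ancestral vertex upstream), which is
what makes trapped (type 2) recombinations in non-ancestral gaps possible.
A Markov-style approximation windows both recombination and recoalescence
candidates to ``[p - w, p + w]`` around the event position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .genealogy import (
    Arg, COAL, Edge, Genealogy, RECOMB, RecombinationMask, StructuralError, Tree,
)
from .intervals import EMPTY, IntervalSet
from .maintenance import NHKey, update_upstream
from .mutscan import next_inconsistent

__all__ = [
    "SweepConfig",
    "RREvent",
    "classify_event",
    "window_filter",
    "apply_rr",
    "try_mco",
    "mco_mask_update",
    "Candidate",
    "sample_ppp_latitude",
    "derived_candidates",
    "wild_candidates",
    "breakpoint_lower_bound",
    "sample_breakpoint",
    "sample_derived_recoalescence",
    "sample_wild_recoalescence_latitude",
    "sample_unrestricted_rr",
    "build_arg",
    "SweepError",
]

_FULL = IntervalSet([(0.0, math.inf)])


class SweepError(RuntimeError):
    """The sweep could not make progress; carries a diagnostic state dump."""


@dataclass(frozen=True)
class SweepConfig:
    """Knobs of the ARG inference sweep.

    ``window``: half-width ``w`` in bp of the Markov window (``inf`` = exact,
    0 = marginal-tree-only candidates).  ``grid_size``: number of nodes of
    the logarithmic latitude grid used for inhomogeneous-Poisson
    recoalescence sampling.
    """

    window: float = math.inf
    seed: int | None = None
    grid_size: int = 25
    max_event_attempts: int = 64
    debug_check: bool = False

    def __post_init__(self):
        if self.window < 0:
            raise ValueError("window width must be >= 0 (or inf)")
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")


@dataclass(frozen=True)
class RREvent:
    kind: str                     # unrestricted | derived | wild | mco
    rec_edge: Edge
    breakpoint: float
    rec_latitude: float
    recoal_edge: Edge | None      # None = recoalescence above the root
    recoal_latitude: float


class Candidate(NamedTuple):
    edge: Edge
    kind: str          # derived | wild
    anchor: Edge       # mutation edge (derived) / wild-branch top (wild)


# ---------------------------------------------------------------------------
# Event classification and windowing


def classify_event(ancestral: IntervalSet, b: float) -> int:
    """Recombination type (1-5) of a breakpoint ``b`` on an edge's material."""
    if ancestral.is_empty():
        return 5
    left = any(a < b for a, _ in ancestral)
    right = any(e > b for _, e in ancestral)
    if left and right:
        return 1 if ancestral.contains(b) else 2
    return 3 if left else 4


def window_filter(edges, p: float, w: float) -> list[Edge]:
    """Drop edges whose ancestral material misses ``[p - w, p + w]``."""
    if math.isinf(w):
        return list(edges)
    return [e for e in edges if e.ancestral.overlaps_interval(p - w, p + w)]


# ---------------------------------------------------------------------------
# Surgery


def _nudge_into(x: float, lo: float, hi: float) -> float:
    if not lo < hi:
        raise StructuralError(f"empty latitude interval ({lo}, {hi})")
    if x <= lo:
        x = np.nextafter(lo, hi)
    if x >= hi:
        x = np.nextafter(hi, lo)
    return float(x)


def apply_rr(g: Arg, ev: RREvent, *, key: NHKey | None = None) -> None:
    """Apply a recombination-and-recoalescence event to ``g`` in place.

    The recombination edge is split at ``rec_latitude`` by a new
    recombination vertex with mask ``{[0, b'), [b', inf)}``; the freed right
    lineage recoalesces either onto ``recoal_edge`` at ``recoal_latitude``
    or, when ``recoal_edge`` is None, above the root (the recoalescence
    vertex becomes the new gMRCA).  Upstream haplotypes and intervals are
    repaired before returning.
    """
    e_r = ev.rec_edge
    if not e_r.alive:
        raise ValueError("recombination edge is not part of the graph")
    l_r = _nudge_into(ev.rec_latitude, g.latitude[e_r.child], g.latitude[e_r.parent])
    if not ev.recoal_latitude > l_r:
        raise ValueError("recoalescence latitude must exceed recombination latitude")
    b = ev.breakpoint
    if not 0.0 < b < math.inf:
        raise ValueError("breakpoint must be finite and positive")

    I = e_r.ancestral
    vr = g.new_vertex(l_r, g.haplotype[e_r.child], RECOMB)
    mask = RecombinationMask(IntervalSet([(0.0, b)]), IntervalSet([(b, math.inf)]))
    g.masks[vr] = mask
    old_parent = e_r.parent
    g.remove_edge(e_r)
    g.add_edge(e_r.child, vr, I, side=e_r.side)
    left_edge = g.add_edge(vr, old_parent, mask.left.intersection(I), side="left")
    right_anc = mask.right.intersection(I)

    e_c = ev.recoal_edge
    if e_c is e_r:
        # the chosen recoalescence span survives as the left parental edge
        e_c = left_edge
    if e_c is None:
        old_root = g.root
        l_c = ev.recoal_latitude
        if l_c <= g.latitude[old_root]:
            raise ValueError("above-root recoalescence below the root latitude")
        vc = g.new_vertex(l_c, g.haplotype[old_root], COAL)
        g.add_edge(old_root, vc, g.vertex_ancestral(old_root))
        right_edge = g.add_edge(vr, vc, right_anc, side="right")
        g.haplotype[vc] = g.recompute_haplotype(vc)
        g.root = vc
        seeds = [left_edge, right_edge]
    else:
        if not e_c.alive:
            raise ValueError("recoalescence edge is not part of the graph")
        l_c = _nudge_into(ev.recoal_latitude,
                          max(l_r, g.latitude[e_c.child]), g.latitude[e_c.parent])
        J = e_c.ancestral
        vc = g.new_vertex(l_c, g.haplotype[e_c.child], COAL)
        old_up = e_c.parent
        g.remove_edge(e_c)
        g.add_edge(e_c.child, vc, J, side=e_c.side)
        right_edge = g.add_edge(vr, vc, right_anc, side="right")
        g.haplotype[vc] = g.recompute_haplotype(vc)
        up_edge = g.add_edge(vc, old_up, J.union(right_anc))
        seeds = [left_edge, up_edge]
    update_upstream(g, seeds, key=key)


def try_mco(g: Arg, cand: Candidate, marker: int, rng: np.random.Generator,
            *, key: NHKey | None = None,
            window: float = math.inf) -> RREvent | None:
    """Attempt a multiple-crossover event on an existing recombination vertex.

    Applicable when the drawn candidate edge is a parental edge of a
    recombination vertex whose mask side owns the ``[T, inf)`` tail, and
    rerouting the focal marker's material through the *other* parental edge
    merges it with an admissible lineage.  On success the masks are edited in
    place (no new vertices) and the applied event is returned; otherwise
    ``None`` and the caller falls back to an ordinary RR event.
    """
    e = cand.edge
    vk = e.child
    if g.kind[vk] != RECOMB or e.side is None:
        return None
    mask = g.masks[vk]
    own = mask.side(e.side)
    if own.is_empty() or not math.isinf(own.max()):
        return None  # this side does not own the genome tail
    tail_start = own.intervals[-1][0]
    p_m = float(g.sample.positions[marker])
    if tail_start >= p_m:
        return None
    other_name = "left" if e.side == "right" else "right"
    other_edge = next(x for x in g.parent_edges[vk] if x.side == other_name)
    want = g.haplotype[vk].bit(marker)
    excl = frozenset({e.id, cand.anchor.id})
    affected = _removal_affected(g, e, marker)
    st, u, hit = _merge_walk(g, other_edge.parent, marker, excl)
    if hit or u in affected or st != want:
        return None
    if not math.isinf(window):
        lo, hi = p_m - window, p_m + window
        if not (other_edge.ancestral.overlaps_interval(lo, hi)
                or e.ancestral.overlaps_interval(lo, hi)):
            return None
    lb = max(_mco_lower_bound(g, marker, e, other_edge), tail_start)
    b2 = sample_breakpoint(lb, p_m, rng, g.sample.positions)
    g.masks[vk] = mco_mask_update(mask, b2)
    base = g.vertex_ancestral(vk)
    for pe in g.parent_edges[vk]:
        pe.ancestral = g.mask_for_edge(pe).intersection(base)
    update_upstream(g, list(g.parent_edges[vk]), key=key)
    return RREvent("mco", e, b2, g.latitude[vk], other_edge, g.latitude[vk])


def mco_mask_update(mask: RecombinationMask, b2: float) -> RecombinationMask:
    """Edit a recombination mask for an additional crossover at ``b2``.

    The side currently owning the genome tail ``[T, inf)`` is intersected
    with ``[0, b2)`` and the other side gains ``[b2, inf)``, so the material
    right of ``b2`` swaps parents.  The result still partitions ``[0, inf)``.
    """
    tail = IntervalSet([(b2, math.inf)])
    head = IntervalSet([(0.0, b2)])
    left_owns_tail = (not mask.left.is_empty()) and math.isinf(mask.left.max())
    if left_owns_tail:
        return RecombinationMask(left=mask.left.intersection(head),
                                 right=mask.right.union(tail))
    return RecombinationMask(left=mask.left.union(tail),
                             right=mask.right.intersection(head))


# ---------------------------------------------------------------------------
# Marginal-tree helpers at the focal marker


def _anc_children(g: Genealogy, p: float) -> dict[int, list[Edge]]:
    out: dict[int, list[Edge]] = {}
    for e in g.iter_edges():
        if e.ancestral.contains(p):
            out.setdefault(e.parent, []).append(e)
    return out


def _branch_up(g, anc, e: Edge, p: float):
    """Top edge of ``e``'s marginal branch and the branching vertex above
    (None when the branch ends at the marginal root)."""
    cur = e
    while True:
        kids = anc.get(cur.parent, ())
        if len(kids) >= 2:
            return cur, cur.parent
        nxt = g.ancestral_parent_edge_at(cur.parent, p)
        if nxt is None:
            return cur, None
        cur = nxt


def _branch_bottom(g, anc, e: Edge) -> int:
    v = e.child
    while True:
        kids = anc.get(v, ())
        if len(kids) != 1:
            return v
        v = kids[0].child


def _branch_edges(g, anc, top: Edge) -> list[Edge]:
    out = [top]
    cur = top
    while True:
        kids = anc.get(cur.child, ())
        if len(kids) != 1:
            return out
        cur = kids[0]
        out.append(cur)


def _merge_walk(g: Genealogy, v: int, marker: int,
                excluded: frozenset) -> tuple[int, int, bool]:
    """Walk mask-routed from vertex ``v`` to the root at the focal marker's
    position.  Returns (allele of the first ancestral vertex encountered,
    that vertex, whether the walk traversed an excluded edge)."""
    p = float(g.sample.positions[marker])
    status = None
    merge_vertex = -1
    u = v
    while True:
        if status is None and g.is_ancestral_vertex_at(u, p):
            status = g.haplotype[u].bit(marker)
            merge_vertex = u
        e = g.parent_edge_at(u, p)
        if e is None:
            if status is None:
                status = g.haplotype[u].bit(marker)
                merge_vertex = u
            return status, merge_vertex, False
        if e.id in excluded:
            return (status if status is not None else -1), merge_vertex, True
        u = e.parent


def _removal_affected(g: Genealogy, e_r: Edge, marker: int) -> frozenset:
    """Vertices whose state at ``marker`` changes when ``e_r``'s material
    there is withdrawn (pre-surgery analysis).

    Removing *derived* material never changes an allele (AND with 1), so the
    set is empty.  Removing *wild* material flips the alleles of the
    contiguous run of upstream vertices whose remaining material-carrying
    children are all derived -- the cascade that lets a single wild event
    eliminate several mutations.  Vertices left without any material are
    included as well.
    """
    p = float(g.sample.positions[marker])
    if not e_r.ancestral.contains(p):
        return frozenset()
    if g.haplotype[e_r.child].bit(marker) == 1:
        return frozenset()
    affected: set[int] = set()
    cur, v = e_r, e_r.parent
    while True:
        others = [x for x in g.child_edges[v]
                  if x is not cur and x.ancestral.contains(p)]
        if others and not all(
                g.haplotype[x.child].bit(marker) == 1 for x in others):
            return frozenset(affected)  # allele stays wild: cascade stops
        affected.add(v)
        e = g.ancestral_parent_edge_at(v, p)
        if e is None:
            return frozenset(affected)
        cur, v = e, e.parent


# ---------------------------------------------------------------------------
# Constrained candidates


def derived_candidates(g: Arg, M, marker: int) -> list[Candidate]:
    """Mutation edges plus their downstream marginally-siblingless chains.

    Recombining any returned edge (breakpoint left of the focal marker) and
    recoalescing with an admissible derived lineage removes exactly one
    mutation edge.
    """
    p = float(g.sample.positions[marker])
    anc = _anc_children(g, p)
    out: list[Candidate] = []
    for me in M:
        out.append(Candidate(me, "derived", me))
        v = me.child
        while True:
            kids = anc.get(v, ())
            if len(kids) != 1:
                break
            out.append(Candidate(kids[0], "derived", me))
            v = kids[0].child
    return out


def wild_candidates(g: Arg, M, marker: int) -> list[Candidate]:
    """Wild branches whose marginal brother and uncle are mutation edges.

    Every edge of a qualifying wild branch is a candidate; extracting its
    focal-marker material makes the brother and uncle siblings, merging two
    derived lineages (and possibly cascading through further derived
    cousins).
    """
    p = float(g.sample.positions[marker])
    anc = _anc_children(g, p)
    out: list[Candidate] = []
    seen: set[int] = set()
    for me in M:
        top, U = _branch_up(g, anc, me, p)
        if U is None:
            continue
        sibs = [x for x in anc[U] if x is not top]
        if len(sibs) != 1:
            continue
        wtop = sibs[0]
        if wtop.id in seen:
            continue
        if g.haplotype[_branch_bottom(g, anc, wtop)].bit(marker) != 0:
            continue  # sibling branch is not wild
        eU = g.ancestral_parent_edge_at(U, p)
        if eU is None:
            continue  # no uncle: U is the marginal root
        topU, U2 = _branch_up(g, anc, eU, p)
        if U2 is None:
            continue
        uncles = [x for x in anc[U2] if x is not topU]
        if len(uncles) != 1:
            continue
        ub = _branch_bottom(g, anc, uncles[0])
        if not (g.haplotype[ub].bit(marker) == 1
                and g.haplotype[U2].bit(marker) == 0):
            continue  # uncle branch is not a mutation branch
        seen.add(wtop.id)
        for e2 in _branch_edges(g, anc, wtop):
            out.append(Candidate(e2, "wild", wtop))
    return out


# ---------------------------------------------------------------------------
# Recoalescence


def _admissible_recoal_edges(g: Arg, marker: int, want: int,
                             excluded: frozenset, window: float,
                             affected: frozenset = frozenset()) -> list[Edge]:
    """Edges a freed lineage with allele ``want`` may recoalesce with
    without creating a mutation at the focal marker.

    ``affected`` holds the vertices whose state the extraction itself
    changes; lineages merging into them are rejected (their pre-event
    alleles are stale)."""
    p = float(g.sample.positions[marker])
    out = []
    for e in g.iter_edges():
        if e.id in excluded:
            continue
        if not math.isinf(window) and not (
                e.ancestral.overlaps_interval(p - window, p + window)):
            continue
        if e.ancestral.contains(p):
            if e.child in affected or g.haplotype[e.child].bit(marker) != want:
                continue
            _, _, hit = _merge_walk(g, e.parent, marker, excluded)
            if hit:
                continue
        else:
            st, u, hit = _merge_walk(g, e.parent, marker, excluded)
            if hit or u in affected or st != want:
                continue
        out.append(e)
    return out


def sample_derived_recoalescence(g: Arg, edges: list[Edge], l_r: float,
                                 rng: np.random.Generator
                                 ) -> tuple[Edge, float] | None:
    """Pick a recoalescence edge with probability proportional to its
    admissible length above ``l_r`` and a Beta(2,2) location on it."""
    if not edges:
        return None
    weights = np.array(
        [max(0.0, g.latitude[e.parent] - max(l_r, g.latitude[e.child]))
         for e in edges])
    tot = weights.sum()
    if tot <= 0:
        return None
    e = edges[int(rng.choice(len(edges), p=weights / tot))]
    lo = max(l_r, g.latitude[e.child])
    hi = g.latitude[e.parent]
    l_c = lo + (hi - lo) * rng.beta(2.0, 2.0)
    return e, float(l_c)


def sample_ppp_latitude(g: Arg, l_r: float, edges: list[Edge],
                        rng: np.random.Generator, grid_size: int = 25,
                        above_root_rate: float = 1.0
                        ) -> tuple[float, bool]:
    """First-event latitude of an inhomogeneous Poisson process whose
    intensity at latitude t is the number of candidate edges overlapping t.

    The cumulative intensity is integrated on a logarithmic latitude grid
    (piecewise-constant intensity from a single pass over edge spans) and
    inverted; beyond the root the intensity is the constant
    ``above_root_rate``.  Returns (latitude, above_root?).
    """
    root_lat = g.latitude[g.root]
    target = rng.exponential(1.0)
    delta = root_lat - l_r
    acc = 0.0
    if delta > 0:
        spans = [(g.latitude[e.child], g.latitude[e.parent]) for e in edges]
        nodes = np.concatenate(
            [[0.0], np.geomspace(max(delta * 1e-9, 1e-300), delta, grid_size)])
        for a, b in zip(nodes[:-1], nodes[1:]):
            mid = l_r + (a + b) / 2.0
            rho = sum(1 for c, pp in spans if c < mid < pp)
            seg = rho * (b - a)
            if rho > 0 and acc + seg >= target:
                return l_r + a + (target - acc) / rho, False
            acc += seg
    return root_lat + (target - acc) / above_root_rate, True


def sample_wild_recoalescence_latitude(g: Arg, l_r: float, edges: list[Edge],
                                       rng: np.random.Generator,
                                       grid_size: int = 25
                                       ) -> tuple[float, bool]:
    """Recoalescence latitude for a wild event (semi-infinite support)."""
    return sample_ppp_latitude(g, l_r, edges, rng, grid_size)


# ---------------------------------------------------------------------------
# Breakpoints


def breakpoint_lower_bound(g: Arg, marker: int, e_r: Edge,
                           recoal_edge: Edge | None) -> float:
    """Leftmost admissible breakpoint for an RR event at the focal marker.

    Scanning markers leftward from the focal one, a marker ``k`` blocks
    further extension unless (1) the recombining and recoalescing lineages
    agree at ``k``, (2) the recombination edge is not ancestral for ``k``,
    or (3) the recoalescence edge is not ancestral for ``k`` and the first
    ancestral vertex upstream matches the recombining lineage.  Returns the
    position of the first blocking marker (0.0 if none blocks).
    """
    positions = g.sample.positions
    v_r = e_r.child
    for k in range(marker - 1, -1, -1):
        pk = float(positions[k])
        if not e_r.ancestral.contains(pk):
            continue  # no material moves at k
        hr = g.haplotype[v_r].bit(k)
        affected = _removal_affected(g, e_r, k)
        if recoal_edge is not None and recoal_edge.ancestral.contains(pk):
            if recoal_edge.child not in affected \
                    and g.haplotype[recoal_edge.child].bit(k) == hr:
                continue
        else:
            start = recoal_edge.parent if recoal_edge is not None else g.root
            st, u, _ = _merge_walk(g, start, k, frozenset())
            if u not in affected and st == hr:
                continue
        return pk
    return 0.0


def _mco_lower_bound(g: Arg, marker: int, moved_edge: Edge,
                     other_edge: Edge) -> float:
    vk = moved_edge.child
    for k in range(marker - 1, -1, -1):
        pk = float(g.sample.positions[k])
        if not moved_edge.ancestral.contains(pk):
            continue
        affected = _removal_affected(g, moved_edge, k)
        st, u, _ = _merge_walk(g, other_edge.parent, k, frozenset())
        if u not in affected and st == g.haplotype[vk].bit(k):
            continue
        return pk
    return 0.0


def sample_breakpoint(b_lo: float, m_pos: float, rng: np.random.Generator,
                      positions=None) -> float:
    """Uniform breakpoint on ``[b_lo, m_pos)``, avoiding exact marker
    positions and the endpoints (half-open tie-breaking)."""
    if not b_lo < m_pos:
        raise StructuralError(f"empty breakpoint support [{b_lo}, {m_pos})")
    for _ in range(64):
        b = float(rng.uniform(b_lo, m_pos))
        if b <= b_lo or b >= m_pos:
            continue
        if positions is not None and b in positions:
            continue
        return b
    # support is numerically degenerate: collapse just left of the marker
    return float(np.nextafter(m_pos, b_lo))


# ---------------------------------------------------------------------------
# Unrestricted events


def sample_unrestricted_rr(g: Arg, rng: np.random.Generator,
                           grid_size: int = 25,
                           window: float = math.inf) -> RREvent:
    """Draw an RR event approximating the coalescent with recombination.

    The recombination edge is length-weighted among edges carrying ancestral
    material; the breakpoint is uniform on the interior of the closure of
    that edge's material, which restricts events to types 1 and 2; the
    location is Beta(2,2) on the edge; recoalescence follows the usual
    inhomogeneous Poisson scheme with a uniformly chosen edge at the
    resulting latitude.
    """
    pool = [e for e in g.iter_edges() if not e.ancestral.is_empty()]
    if not pool:
        raise SweepError("no edge carries ancestral material")
    lengths = np.array([e.length(g) for e in pool])
    e_r = pool[int(rng.choice(len(pool), p=lengths / lengths.sum()))]
    r_l, r_u = e_r.ancestral.min(), e_r.ancestral.max()
    if not r_l < r_u:
        raise SweepError("degenerate ancestral closure")
    while True:
        b = float(rng.uniform(r_l, r_u))
        if r_l < b < r_u:
            break
    l_r = (g.latitude[e_r.child]
           + e_r.length(g) * float(rng.beta(2.0, 2.0)))
    cands = window_filter(g.iter_edges(), b, window)
    for _ in range(32):
        l_c, above = sample_ppp_latitude(g, l_r, cands, rng, grid_size)
        if above:
            return RREvent("unrestricted", e_r, b, l_r, None, l_c)
        at = [e for e in cands
              if g.latitude[e.child] < l_c < g.latitude[e.parent]]
        if at:
            e_c = at[int(rng.integers(len(at)))]
            return RREvent("unrestricted", e_r, b, l_r, e_c, l_c)
    raise SweepError("failed to place an unrestricted recoalescence")


# ---------------------------------------------------------------------------
# The sweep


def _one_constrained_event(g: Arg, marker: int, M, cfg: SweepConfig,
                           rng: np.random.Generator, key: NHKey) -> RREvent:
    """Generate and apply one mutation-reducing event at the focal marker."""
    p_m = float(g.sample.positions[marker])
    before = len(M)
    cands = derived_candidates(g, M, marker) + wild_candidates(g, M, marker)
    cands = [c for c in cands
             if math.isinf(cfg.window)
             or c.edge.ancestral.overlaps_interval(p_m - cfg.window,
                                                   p_m + cfg.window)]
    if not cands:
        raise SweepError(f"no candidate recombination edge at marker {marker + 1}")
    pool = list(cands)
    for _ in range(cfg.max_event_attempts):
        if not pool:
            raise SweepError(
                f"no viable candidate recombination edge at marker {marker + 1}")
        weights = np.array([c.edge.length(g) for c in pool])
        cand = pool[int(rng.choice(len(pool), p=weights / weights.sum()))]
        ev = try_mco(g, cand, marker, rng, key=key, window=cfg.window)
        if ev is not None:
            after = g.mutation_count_at(marker)
            if not after < before:
                raise SweepError(
                    f"MCO event failed to reduce mutations at marker {marker + 1}"
                    f" ({before} -> {after})")
            return ev
        e_r = cand.edge
        l_r = (g.latitude[e_r.child]
               + e_r.length(g) * float(rng.beta(2.0, 2.0)))
        want = 1 if cand.kind == "derived" else 0
        excl = frozenset({e_r.id, cand.anchor.id})
        affected = _removal_affected(g, e_r, marker)
        adm = _admissible_recoal_edges(g, marker, want, excl, cfg.window,
                                       affected)
        if cand.kind == "derived":
            pick = sample_derived_recoalescence(g, adm, l_r, rng)
            if pick is None and adm:
                # every admissible span ends below l_r: redraw the
                # recombination latitude under the admissible cap
                cap = max(g.latitude[e.parent] for e in adm)
                lo, hi = g.latitude[e_r.child], min(g.latitude[e_r.parent], cap)
                if hi > lo:
                    l_r = _nudge_into(lo + (hi - lo) * float(rng.beta(2.0, 2.0)),
                                      lo, hi)
                    pick = sample_derived_recoalescence(g, adm, l_r, rng)
            if pick is None:
                # sterile candidate: no admissible recoalescence can sit
                # above any recombination latitude on this edge
                pool.remove(cand)
                continue
            e_c, l_c = pick
        else:
            placed = False
            for _ in range(8):
                l_c, above = sample_wild_recoalescence_latitude(
                    g, l_r, adm, rng, cfg.grid_size)
                if above:
                    e_c = None
                    placed = True
                    break
                at = [e for e in adm
                      if g.latitude[e.child] < l_c < g.latitude[e.parent]]
                if at:
                    e_c = at[int(rng.integers(len(at)))]
                    placed = True
                    break
            if not placed:
                continue
        b_lo = breakpoint_lower_bound(g, marker, e_r, e_c)
        b_lo = max(b_lo, e_r.ancestral.min())  # discard type-4 outcomes
        b = sample_breakpoint(b_lo, p_m, rng, g.sample.positions)
        ev = RREvent(cand.kind, e_r, b, l_r, e_c, l_c)
        apply_rr(g, ev, key=key)
        after = g.mutation_count_at(marker)
        if not after < before:
            raise SweepError(
                f"{cand.kind} event failed to reduce mutations at marker"
                f" {marker + 1} ({before} -> {after})")
        return ev
    raise SweepError(
        f"exhausted {cfg.max_event_attempts} attempts at marker {marker + 1}")


def build_arg(tree: Tree, cfg: SweepConfig | None = None,
              rng: np.random.Generator | None = None) -> Arg:
    """Infer a sample-consistent ARG from an initial coalescent tree.

    Sweeps the markers left to right; at each marker whose marginal tree has
    two or more mutation edges, constrained events are generated until a
    single mutation edge remains, each strictly decreasing the count (so at
    most ``|M| - 1`` events per marker).  The input tree is not modified.
    """
    cfg = cfg or SweepConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    g = Arg.from_tree(tree)
    g.hash_key = NHKey(cfg.seed if cfg.seed is not None else 0)
    g.events = []
    s = g.sample.s
    cursor = 1
    while cursor <= s:
        res = next_inconsistent(g, cursor)
        if res is None:
            break
        marker = res.marker_index - 1
        guard = 0
        while True:
            M = g.mutation_edges_at(marker)
            if len(M) <= 1:
                break
            guard += 1
            if guard > s * g.sample.n + 64:
                raise SweepError(f"runaway event loop at marker {marker + 1}")
            ev = _one_constrained_event(g, marker, M, cfg, rng, g.hash_key)
            g.events.append(ev)
            if cfg.debug_check:
                for k in range(marker):
                    if g.mutation_count_at(k) > 1:
                        raise SweepError(
                            f"event at marker {marker + 1} broke marker {k + 1}")
        cursor = marker + 2
    return g
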