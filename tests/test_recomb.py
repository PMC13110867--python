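import math

import numpy as np
import pytest
from scipy import stats as sps

from argsweep import (
    Arg, Metric, RREvent, SweepConfig, TreeBuildConfig, build_arg, build_tree,
    classify_event, is_consistent, marginal_tree, sample_unrestricted_rr,
    validate, window_filter,
)
from argsweep.genealogy import RECOMB, RecombinationMask
from argsweep.intervals import EMPTY, IntervalSet
from argsweep.recomb import (
    _admissible_recoal_edges, _removal_affected, apply_rr, breakpoint_lower_bound,
    derived_candidates, mco_mask_update, sample_breakpoint,
    sample_derived_recoalescence, sample_ppp_latitude, wild_candidates,
)
from conftest import make_sample, random_samples
from test_genealogy import manual_tree


# ---------------------------------------------------------------------------
# classification, windowing, masks


def test_classify_event_types():
    assert classify_event(IntervalSet([(0, 10)]), 5.0) == 1
    assert classify_event(IntervalSet([(0, 4), (6, 10)]), 5.0) == 2
    assert classify_event(IntervalSet([(0, 4)]), 5.0) == 3
    assert classify_event(IntervalSet([(6, 10)]), 5.0) == 4
    assert classify_event(EMPTY, 5.0) == 5


def test_window_filter_formula():
    class E:
        def __init__(self, iv):
            self.ancestral = IntervalSet(iv)

    e = E([(0, 5)])
    assert window_filter([e], 10.0, 2.0) == []          # [8,12] misses [0,5)
    assert window_filter([e], 6.0, 2.0) == [e]          # [4,8] overlaps
    assert window_filter([e], 1e9, math.inf) == [e]     # identity


def test_mco_mask_worked_formulas():
    m0 = RecombinationMask(IntervalSet([(0, 3)]), IntervalSet([(3, math.inf)]))
    m1 = mco_mask_update(m0, 7.0)
    assert m1.left == IntervalSet([(0, 3), (7, math.inf)])
    assert m1.right == IntervalSet([(3, 7)])
    m2 = mco_mask_update(m1, 9.0)
    assert m2.left == IntervalSet([(0, 3), (7, 9)])
    assert m2.right == IntervalSet([(3, 7), (9, math.inf)])
    for m in (m0, m1, m2):  # masks always partition the genome
        assert m.left.union(m.right) == IntervalSet([(0, math.inf)])
        assert m.left.intersection(m.right) == EMPTY


# ---------------------------------------------------------------------------
# surgery


def _four_leaf_tree():
    sample = make_sample(["10", "10", "01", "01"], positions=[10.0, 40.0],
                         l=50.0)
    return sample, manual_tree(sample, [(0, 1), (2, 3), (4, 5)],
                               [0.5, 1.0, 2.0])


def test_apply_rr_counting_invariant_and_validate():
    sample, tree = _four_leaf_tree()
    g = Arg.from_tree(tree)
    n = sample.n
    for i, (child, target) in enumerate([(0, 2), (1, 3)]):
        e_r = next(e for e in g.iter_edges() if e.child == child)
        e_c = next(e for e in g.iter_edges() if e.child == target)
        apply_rr(g, RREvent("unrestricted", e_r, 25.0, 0.25, e_c, 0.75 + 0.01 * i))
        n_coal = sum(1 for k in g.kind if k == "coalescence")
        assert n_coal == g.n_recombinations() + n - 1
        validate(g)


def test_recoalescence_above_root_promotes_new_gmrca():
    sample, tree = _four_leaf_tree()
    g = Arg.from_tree(tree)
    old_root = g.root
    e_r = next(e for e in g.iter_edges() if e.child == 0)
    apply_rr(g, RREvent("unrestricted", e_r, 25.0, 0.25, None, 3.5))
    assert g.root != old_root
    assert g.latitude[g.root] == 3.5
    # the old root gained a parent and keeps its haplotype
    assert len(g.parent_edges[old_root]) == 1
    validate(g)


def test_marginal_trees_left_of_breakpoint_unchanged():
    sample, tree = _four_leaf_tree()
    g = Arg.from_tree(tree)
    before = marginal_tree(g, 10.0).parent_of
    e_r = next(e for e in g.iter_edges() if e.child == 0)
    e_c = next(e for e in g.iter_edges() if e.child == 2)
    apply_rr(g, RREvent("unrestricted", e_r, 25.0, 0.25, e_c, 0.75))
    assert marginal_tree(g, 10.0).parent_of == before
    assert marginal_tree(g, 40.0).parent_of != before


# ---------------------------------------------------------------------------
# unrestricted events


def test_unrestricted_edge_choice_proportional_to_length(rng):
    sample = make_sample(["1", "1", "0"], positions=[5.0], l=10.0)
    tree = manual_tree(sample, [(0, 1), (2, 3)], [0.4, 2.0])
    g = Arg.from_tree(tree)
    edges = list(g.iter_edges())
    lengths = np.array([e.length(g) for e in edges])
    ids = {e.id: i for i, e in enumerate(edges)}
    n = 20_000
    counts = np.zeros(len(edges))
    for _ in range(n):
        ev = sample_unrestricted_rr(g, rng)
        counts[ids[ev.rec_edge.id]] += 1
        assert ev.recoal_latitude > ev.rec_latitude
    expect = n * lengths / lengths.sum()
    assert sps.chisquare(counts, f_exp=expect).pvalue > 1e-4


def test_unrestricted_location_beta_symmetry(rng):
    sample = make_sample(["1", "0"], positions=[5.0], l=10.0)
    tree = manual_tree(sample, [(0, 1)], [1.0])
    g = Arg.from_tree(tree)
    locs = [sample_unrestricted_rr(g, rng).rec_latitude for _ in range(5000)]
    # Beta(2,2) on (0,1): mean at the edge midpoint
    assert np.mean(locs) == pytest.approx(0.5, abs=0.02)


def test_unrestricted_events_are_type_1_or_2_only(rng):
    # an ARG whose edges carry interval gaps
    for sample in random_samples(2, rng, n_max=8):
        g = build_arg(build_tree(sample, TreeBuildConfig(seed=3), rng),
                      SweepConfig(seed=3), rng)
        if g.n_recombinations() == 0:
            continue
        for _ in range(2000):
            ev = sample_unrestricted_rr(g, rng)
            t = classify_event(ev.rec_edge.ancestral, ev.breakpoint)
            assert t in (1, 2)


# ---------------------------------------------------------------------------
# breakpoints


def test_sample_breakpoint_uniform_and_strict(rng):
    draws = np.array([sample_breakpoint(2.0, 7.0, rng) for _ in range(10_000)])
    assert draws.min() > 2.0 and draws.max() < 7.0
    assert sps.kstest(draws, sps.uniform(2.0, 5.0).cdf).pvalue > 1e-4
    # support collapse: a degenerate interval still yields b just left of m
    b = sample_breakpoint(np.nextafter(7.0, 0.0), 7.0, rng)
    assert np.nextafter(7.0, 0.0) <= b < 7.0


def test_breakpoint_bound_extends_to_zero_when_lineages_agree():
    # recombining and recoalescing child haplotypes equal at all left markers
    sample = make_sample(["111", "110", "011", "010"],
                         positions=[10.0, 20.0, 30.0], l=40.0)
    tree = manual_tree(sample, [(0, 1), (2, 3), (4, 5)], [1.0, 1.5, 2.0])
    g = Arg.from_tree(tree)
    e_r = next(e for e in g.iter_edges() if e.child == 0)   # 111
    e_c = next(e for e in g.iter_edges() if e.child == 2)   # 011 differs at 1
    # marker 3 focal: markers 1,2 to check; marker 2 agrees (1 == 1),
    # marker 1 disagrees (1 vs 0) -> bound stops at position 10
    assert breakpoint_lower_bound(g, 2, e_r, e_c) == 10.0
    e_c2 = next(e for e in g.iter_edges() if e.child == 1)  # 110 agrees at 1,2
    assert breakpoint_lower_bound(g, 2, e_r, e_c2) == 0.0


def test_breakpoint_bound_ignores_non_ancestral_markers():
    sample, tree = _four_leaf_tree()
    g = Arg.from_tree(tree)
    e_r = next(e for e in g.iter_edges() if e.child == 0)
    e_c = next(e for e in g.iter_edges() if e.child == 2)
    apply_rr(g, RREvent("unrestricted", e_r, 25.0, 0.25, e_c, 0.75))
    # the right parental edge of the new recombination vertex is not
    # ancestral for marker 1 ([0, 25) went left): no constraint from it
    vr = next(v for v in range(g.n_vertices) if g.kind[v] == RECOMB)
    right = next(e for e in g.parent_edges[vr] if e.side == "right")
    assert not right.ancestral.contains(10.0)
    some_target = next(e for e in g.iter_edges()
                       if e is not right and g.latitude[e.parent] > g.latitude[right.child])
    assert breakpoint_lower_bound(g, 1, right, some_target) <= 25.0


def test_rr_at_admissible_breakpoint_never_increases_left_counts(rng):
    """Fuzz: apply a constrained event through the public sweep with debug
    checking on -- every event must strictly reduce the focal count and
    never resurrect an inconsistency left of the cursor."""
    for sample in random_samples(6, rng, n_max=12):
        g = build_arg(build_tree(sample, TreeBuildConfig(seed=1), rng),
                      SweepConfig(seed=1, debug_check=True), rng)
        assert is_consistent(g)[0]


# ---------------------------------------------------------------------------
# constrained candidates and recoalescence


def test_derived_candidates_on_plain_tree_equal_mutation_edges():
    sample = make_sample(["11", "10", "01", "00"])
    tree = manual_tree(sample, [(0, 1), (2, 3), (4, 5)], [1.0, 1.5, 2.0])
    g = Arg.from_tree(tree)
    M = g.mutation_edges_at(1)
    assert len(M) == 2
    cands = derived_candidates(g, M, 1)
    # leaves below the mutation edges are leaf edges: chains stop immediately
    # except the leaf edge itself when the mutation edge sits above a leaf
    edges = {c.edge.id for c in cands}
    assert {m.id for m in M} <= edges
    for c in cands:
        assert g.haplotype[c.edge.child].bit(1) == 1


def test_every_derived_candidate_reduces_count_by_one(rng):
    sample = make_sample(["11", "10", "01", "00"])
    for trial in range(30):
        tree = manual_tree(sample, [(0, 1), (2, 3), (4, 5)], [1.0, 1.5, 2.0])
        g = Arg.from_tree(tree)
        M = g.mutation_edges_at(1)
        before = len(M)
        cands = derived_candidates(g, M, 1)
        cand = cands[int(rng.integers(len(cands)))]
        affected = _removal_affected(g, cand.edge, 1)
        adm = _admissible_recoal_edges(
            g, 1, 1, frozenset({cand.edge.id, cand.anchor.id}), math.inf,
            affected)
        pick = sample_derived_recoalescence(
            g, adm, g.latitude[cand.edge.child] + 1e-6, rng)
        if pick is None:
            continue
        e_c, l_c = pick
        lo = breakpoint_lower_bound(g, 1, cand.edge, e_c)
        lo = max(lo, cand.edge.ancestral.min())
        b = sample_breakpoint(lo, float(sample.positions[1]), rng)
        l_r = g.latitude[cand.edge.child] + 1e-6
        apply_rr(g, RREvent("derived", cand.edge, b, l_r, e_c, l_c))
        assert g.mutation_count_at(1) == before - 1
        validate(g)


def test_wild_candidates_require_mutation_brother_and_uncle():
    # ((0:1, 1:1), 2:0) with an outgroup 3:0 at the top: the wild leaf 2's
    # brother is the derived cherry (mutation branch) and its uncle is the
    # 3-branch -- wild, so no wild candidate exists
    sample = make_sample(["1", "1", "0", "0"], positions=[5.0], l=10.0)
    tree = manual_tree(sample, [(0, 1), (4, 2), (5, 3)], [1.0, 1.5, 2.0])
    g = Arg.from_tree(tree)
    M = g.mutation_edges_at(0)
    assert len(M) == 1
    # derived cousins topology: ((0:1, 1:1), (2:1, 3:0)) -- recombining the
    # wild leaf 3 merges the derived cherry with derived leaf 2
    sample2 = make_sample(["1", "1", "1", "0", "0"], positions=[5.0], l=10.0)
    tree2 = manual_tree(sample2, [(0, 1), (2, 3), (5, 6), (7, 4)],
                        [1.0, 1.2, 1.6, 2.0])
    g2 = Arg.from_tree(tree2)
    M2 = g2.mutation_edges_at(0)
    assert len(M2) == 2
    wc = wild_candidates(g2, M2, 0)
    assert len(wc) == 1
    assert wc[0].edge.child == 3  # the wild leaf inside the mixed cherry


def test_wild_event_eliminates_two_mutations_in_derived_cousins(rng):
    """A single wild RR on the derived-cousins topology takes the focal
    count from 3 to 1: the brother/uncle merge cascades."""
    # caterpillar ((((d1, w), d2), d3), out): recombining the wild leaf w
    # merges three derived lineages; the cascade stops at the wild outgroup
    rows = ["1", "0", "1", "1", "0"]
    sample = make_sample(rows, positions=[5.0], l=10.0)
    tree = manual_tree(sample, [(0, 1), (5, 2), (6, 3), (7, 4)],
                       [1.0, 1.5, 2.0, 2.5])
    g = Arg.from_tree(tree)
    M = g.mutation_edges_at(0)
    assert len(M) == 3
    wc = wild_candidates(g, M, 0)
    assert any(c.edge.child == 1 for c in wc)
    cand = next(c for c in wc if c.edge.child == 1)
    affected = _removal_affected(g, cand.edge, 0)
    assert len(affected) >= 3  # the cascade reaches past the brother merge
    adm = _admissible_recoal_edges(
        g, 0, 0, frozenset({cand.edge.id, cand.anchor.id}), math.inf, affected)
    assert adm
    l_r = 0.5
    l_c, above = sample_ppp_latitude(g, l_r, adm, rng)
    e_c = None
    if not above:
        at = [e for e in adm if g.latitude[e.child] < l_c < g.latitude[e.parent]]
        e_c = at[0] if at else None
    if e_c is None:
        l_c = g.latitude[g.root] + 0.5
    apply_rr(g, RREvent("wild", cand.edge, 2.5, l_r, e_c, l_c))
    assert g.mutation_count_at(0) == 1
    validate(g)


def test_derived_recoalescence_weights_by_admissible_length(rng):
    sample = make_sample(["1", "1", "1", "0"], positions=[5.0], l=10.0)
    # caterpillar: derived leaves 0,1,2; lengths of admissible edges differ
    tree = manual_tree(sample, [(0, 1), (4, 2), (5, 3)], [1.0, 4.0, 8.0])
    g = Arg.from_tree(tree)
    edges = {e.child: e for e in g.iter_edges()}
    cands = [edges[0], edges[1]]   # leaf edges of lengths 1 and 1... use 2
    l_r = 0.0
    # admissible lengths above l_r: leaf0 -> 1.0, vertex4 -> 3.0
    pool = [edges[0], edges[4]]
    hits = {0: 0, 4: 0}
    for _ in range(8000):
        e, l_c = sample_derived_recoalescence(g, pool, l_r, rng)
        hits[e.child] += 1
        assert l_c > l_r
    frac = hits[4] / 8000
    assert abs(frac - 0.75) < 4 * math.sqrt(0.25 * 0.75 / 8000)


def test_ppp_latitude_homogeneous_limit_matches_exponential(rng):
    # two parallel edges spanning (0, 50): intensity 2 everywhere below root
    sample = make_sample(["1", "0"], positions=[5.0], l=10.0)
    tree = manual_tree(sample, [(0, 1)], [50.0])
    g = Arg.from_tree(tree)
    edges = list(g.iter_edges())
    draws = np.array([sample_ppp_latitude(g, 0.0, edges, rng)[0]
                      for _ in range(5000)])
    below = draws[draws < 50.0]
    assert len(below) > 4900
    assert sps.kstest(below, sps.expon(scale=0.5).cdf).pvalue > 1e-4


def test_ppp_latitude_grid_refinement_agrees(rng):
    sample = random_samples(1, rng, n_max=10)[0]
    g = build_arg(build_tree(sample, TreeBuildConfig(seed=5), rng),
                  SweepConfig(seed=5), rng)
    edges = list(g.iter_edges())
    l_r = g.latitude[g.root] * 0.05
    a = np.array([sample_ppp_latitude(g, l_r, edges, rng, 25)[0]
                  for _ in range(4000)])
    b = np.array([sample_ppp_latitude(g, l_r, edges, rng, 500)[0]
                  for _ in range(4000)])
    assert sps.ks_2samp(a, b).pvalue > 1e-4


def test_ppp_latitude_is_always_finite(rng):
    sample = make_sample(["1", "0"], positions=[5.0], l=10.0)
    tree = manual_tree(sample, [(0, 1)], [0.3])
    g = Arg.from_tree(tree)
    draws = [sample_ppp_latitude(g, 0.2, list(g.iter_edges()), rng)[0]
             for _ in range(2000)]
    assert np.all(np.isfinite(draws))


# ---------------------------------------------------------------------------
# the sweep


def test_already_consistent_sample_needs_no_recombination(rng):
    sample = make_sample(["1", "1", "0", "0"], positions=[5.0], l=10.0)
    cfg = TreeBuildConfig(metric=Metric("left", math.inf))
    for _ in range(10):
        tree = build_tree(sample, cfg, rng)
        g = build_arg(tree, SweepConfig(), rng)
        assert g.n_recombinations() == 0
        assert is_consistent(g)[0]


def test_four_gamete_sample_forces_recombination(rng, four_gamete_sample):
    for seed in range(5):
        tree = build_tree(four_gamete_sample, TreeBuildConfig(seed=seed))
        g = build_arg(tree, SweepConfig(seed=seed))
        assert g.n_recombinations() >= 1
        assert is_consistent(g)[0]
        validate(g)


@pytest.mark.parametrize("window", [0.0, 5000.0, math.inf])
def test_sweep_consistent_under_any_window(rng, window):
    for sample in random_samples(3, rng, n_max=12):
        tree = build_tree(sample, TreeBuildConfig(seed=4), rng)
        g = build_arg(tree, SweepConfig(seed=4, window=window), rng)
        validate(g)
        assert is_consistent(g)[0]


def test_build_arg_does_not_modify_input_tree(rng):
    sample = random_samples(1, rng, n_max=8)[0]
    tree = build_tree(sample, TreeBuildConfig(seed=6), rng)
    n_edges = tree.n_edges
    heights = list(tree.latitude)
    build_arg(tree, SweepConfig(seed=6), rng)
    assert tree.n_edges == n_edges and tree.latitude == heights
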