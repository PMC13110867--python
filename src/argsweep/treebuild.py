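"""Initial coalescent tree construction.

The tree is grown by repeated coalescence of *live* vertices.  One partner
``v_a`` is drawn uniformly; the other is drawn with probability proportional
to the unnormalized Poisson weight

    p_ab = mu^{d_ab} / Gamma(d_ab + 1),

where ``d_ab = c0 * d(h_a, h_b)`` is the (biased) haplotype pseudodistance
and ``mu`` the global mutation rate.  Sampling works entirely on the log
scale through the Gumbel-max trick: ``argmax_k {log p_k + g_k}`` with iid
standard Gumbel noise ``g_k`` is categorical with probabilities
proportional to ``p_k``, so no normalizing constant is ever formed.

An approximate variant, *secretary sampling*, trades exactness for early
termination: a learning fraction ``t0`` of the (randomly permuted)
candidates is observed, then the first candidate beating the learning-phase
record is returned.  The probability of early termination is ``1 - t0`` and,
for many candidates, the probability of returning the exact sample tends to
``t0 * (1 - log t0)``.

The coalesced haplotype is the Hadamard (elementwise GF(2)) product of its
children's and the latitude increment is Exp(#live vertices).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.special import gammaln, logsumexp

from .bitseq import Metric, Sample, biased_distance
from .genealogy import COAL, Tree
from .intervals import IntervalSet

__all__ = [
    "TreeBuildConfig",
    "coal_log_weight",
    "gumbel_argmax_select",
    "secretary_select",
    "SecretaryResult",
    "build_tree",
    "tree_log_density",
    "NoCandidateError",
]


class NoCandidateError(RuntimeError):
    """Every candidate has zero weight."""


@dataclass(frozen=True)
class TreeBuildConfig:
    metric: Metric = field(default_factory=Metric)
    t0: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 < self.t0 <= 1.0:
            raise ValueError("t0 must lie in (0, 1]")


def coal_log_weight(d_ab: float, mu: float) -> float:
    """``log p_ab = d_ab * log(mu) - log Gamma(d_ab + 1)``.

    ``log Gamma`` is evaluated exactly (library log-gamma); Stirling's
    formula is only its asymptotic expansion.  ``d_ab = inf`` gives weight
    zero (-inf).
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if d_ab < 0:
        raise ValueError("distance must be nonnegative")
    if math.isinf(d_ab):
        return -math.inf
    return d_ab * math.log(mu) - float(gammaln(d_ab + 1.0))


def gumbel_argmax_select(log_weights, rng: np.random.Generator) -> int:
    """Sample a categorical index with probabilities ∝ exp(log_weights)."""
    lw = np.asarray(log_weights, dtype=float)
    if lw.size == 0 or not np.any(np.isfinite(lw)):
        raise NoCandidateError("all candidate weights are zero")
    return int(np.argmax(lw + rng.gumbel(size=lw.size)))


class SecretaryResult(NamedTuple):
    index: int
    traversed: int
    early: bool


def secretary_select(log_weights, t0: float,
                     rng: np.random.Generator) -> SecretaryResult:
    """Approximate Gumbel-max selection with early termination.

    Candidates are consumed in the order given (callers wanting the scheme's
    guarantees must stream them in uniformly random order).  The first
    ``ceil(t0 * m)`` perturbed values set a record; afterwards the first
    value exceeding the record is returned immediately.  If none does, the
    overall argmax is returned after full traversal.  ``t0 = 1`` is exact.
    """
    if not 0.0 < t0 <= 1.0:
        raise ValueError("t0 must lie in (0, 1]")
    lw = np.asarray(log_weights, dtype=float)
    m = lw.size
    if m == 0 or not np.any(np.isfinite(lw)):
        raise NoCandidateError("all candidate weights are zero")
    pert = lw + rng.gumbel(size=m)
    learn = math.ceil(t0 * m)
    best = int(np.argmax(pert[:learn]))
    record = pert[best]
    for k in range(learn, m):
        if pert[k] > record:
            return SecretaryResult(k, k + 1, True)
    if learn < m:
        best = int(np.argmax(pert))
    return SecretaryResult(best, m, False)


def build_tree(sample: Sample, cfg: TreeBuildConfig | None = None,
               rng: np.random.Generator | None = None) -> Tree:
    """Construct a coalescent tree for ``sample``.

    Returns a :class:`~argsweep.genealogy.Tree` whose internal haplotypes
    satisfy the AND rule and whose ``log_density`` accumulates the latitude
    and partner-selection terms.
    """
    cfg = cfg or TreeBuildConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = sample.n
    if n < 2:
        raise ValueError("need at least two haplotypes")
    mu = sample.mu
    full = IntervalSet([(0.0, sample.seq_length)])
    tree = Tree(sample)
    tree.meta = {"seed": cfg.seed, "t0": cfg.t0,
                 "metric": cfg.metric.kind, "c0": cfg.metric.c0}
    live = list(range(n))
    lat = 0.0
    while len(live) > 1:
        k = len(live)
        dt = rng.exponential(1.0 / k)
        lat += dt
        tree.density_terms.append(("latitude", math.log(k) - k * dt))

        order = rng.permutation(k)
        va = live[int(order[0])]
        cand_pool = [live[int(i)] for i in order[1:]]
        lws = np.array(
            [coal_log_weight(
                biased_distance(cfg.metric, tree.haplotype[va],
                                tree.haplotype[c]), mu)
             for c in cand_pool])
        if not np.any(np.isfinite(lws)):
            # Zero-weight dead end under a hard (c0 = inf) bias: prefer a
            # first partner that has at least one admissible mate, falling
            # back to a forced uniform pairing for the final cross-class join.
            va, cand_pool, lws = _rescue_zero_weights(tree, cfg, mu, live, rng)
        if np.any(np.isfinite(lws)):
            res = secretary_select(lws, cfg.t0, rng)
            vb = cand_pool[res.index]
            norm = float(logsumexp(lws[:res.traversed]))
            tree.density_terms.append(("partner", float(lws[res.index]) - norm))
        else:
            vb = cand_pool[int(rng.integers(len(cand_pool)))]
            tree.density_terms.append(("partner", -math.log(len(cand_pool))))

        hv = tree.haplotype[va] & tree.haplotype[vb]
        vc = tree.new_vertex(lat, hv, COAL)
        tree.add_edge(va, vc, full)
        tree.add_edge(vb, vc, full)
        live.remove(va)
        live.remove(vb)
        live.append(vc)
    tree.root = live[0]
    tree.log_density = sum(t for _, t in tree.density_terms)
    return tree


def _rescue_zero_weights(tree, cfg, mu, live, rng):
    """Find a uniformly chosen first partner that has a finite-weight mate."""
    perm = rng.permutation(len(live))
    for i in perm:
        va = live[int(i)]
        cand = [c for c in live if c != va]
        lws = np.array(
            [coal_log_weight(
                biased_distance(cfg.metric, tree.haplotype[va],
                                tree.haplotype[c]), mu)
             for c in cand])
        if np.any(np.isfinite(lws)):
            rng.shuffle(cand)  # candidate order must stay exchangeable
            lws = np.array(
                [coal_log_weight(
                    biased_distance(cfg.metric, tree.haplotype[va],
                                    tree.haplotype[c]), mu)
                 for c in cand])
            return va, cand, lws
    va = live[int(perm[0])]
    cand = [c for c in live if c != va]
    return va, cand, np.full(len(cand), -math.inf)


def tree_log_density(tree: Tree) -> float:
    """Log-density of a tree built by :func:`build_tree`."""
    if not isinstance(tree, Tree) or not tree.density_terms:
        raise ValueError("tree was not built by build_tree (no recorded terms)")
    return float(sum(t for _, t in tree.density_terms))
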