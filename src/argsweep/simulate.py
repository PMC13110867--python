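"""Synthetic samples: msprime front-end and a built-in Hudson fallback.

The preferred generator delegates to msprime (standard coalescent ancestry,
binary infinite-sites mutations on a continuous genome).  A compact
self-contained implementation of Hudson's coalescent with recombination is
also provided; it tracks, per lineage, the ancestral segments together with
the subtended leaf set, removes fully coalesced material, and superimposes
infinite-sites mutations event-by-event.  It exists both as a dependency-free
fixture source and as an independent cross-check of the msprime path
(Watterson's segregating-site and pairwise-diversity expectations hold for
both).

All rates follow the diploid convention used throughout the package:
``theta = 4 * Ne * mu_prime * l`` and ``rho = 4 * Ne * r * l``; time is
measured in units of ``2 Ne`` generations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bitseq import Sample, Sequence

__all__ = ["SimSpec", "simulate_sample", "synthetic_kreitman_scale_sample"]

_MAX_EVENTS = 100_000


@dataclass(frozen=True)
class SimSpec:
    """Parameters of a synthetic sample draw.

    ``n`` haploid sequences of length ``l`` bp from a diploid population of
    effective size ``Ne``, with per-bp per-generation mutation and
    recombination rates ``mu_prime`` and ``rho``.
    """

    n: int
    l: float = 1e5
    Ne: float = 1e4
    mu_prime: float = 1e-8
    rho: float = 1e-8
    seed: int | None = None

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need n >= 2")
        if min(self.l, self.Ne) <= 0 or min(self.mu_prime, self.rho) < 0:
            raise ValueError("rates must be nonnegative, sizes positive")


def simulate_sample(spec: SimSpec, engine: str = "msprime",
                    return_truth: bool = False):
    """Draw a sample of phased, polarized haplotypes.

    ``engine="msprime"`` uses the external simulator and can return the true
    tree sequence for accuracy experiments; ``engine="builtin"`` uses the
    self-contained Hudson implementation (truth reported as an event-count
    summary only).
    """
    if engine == "msprime":
        return _simulate_msprime(spec, return_truth)
    if engine == "builtin":
        return _simulate_builtin(spec, return_truth)
    raise ValueError(f"unknown engine {engine!r}")


def _seed_pair(seed):
    rng = np.random.default_rng(seed)
    return [int(x) for x in rng.integers(1, 2**31 - 1, size=2)]


def _simulate_msprime(spec: SimSpec, return_truth: bool):
    import msprime

    s1, s2 = _seed_pair(spec.seed)
    ts = msprime.sim_ancestry(
        samples=[msprime.SampleSet(spec.n, ploidy=1)],
        ploidy=2,
        population_size=spec.Ne,
        sequence_length=spec.l,
        recombination_rate=spec.rho,
        random_seed=s1,
    )
    mts = msprime.sim_mutations(
        ts, rate=spec.mu_prime, model=msprime.BinaryMutationModel(),
        discrete_genome=False, random_seed=s2)
    positions, columns = [], []
    for var in mts.variants():
        geno = np.asarray(var.genotypes)
        if geno.min() == geno.max():
            continue  # non-segregating
        positions.append(var.site.position)
        columns.append(geno)
    sample = _to_sample(np.array(columns, dtype=np.int8), positions, spec)
    return (sample, mts) if return_truth else sample


def _to_sample(matrix, positions, spec: SimSpec) -> Sample:
    # matrix: (s, n)
    seqs = [Sequence.from_bits(matrix[:, j]) for j in range(spec.n)]
    return Sample(seqs, np.asarray(positions, dtype=float), spec.l,
                  spec.mu_prime, spec.Ne)


# ---------------------------------------------------------------------------
# Built-in Hudson coalescent with recombination


class _Lineage:
    __slots__ = ("segments",)

    def __init__(self, segments):
        # segments: list of (a, b, leafmask), disjoint, sorted
        self.segments = segments

    def measure(self):
        return sum(b - a for a, b, _ in self.segments)

    def span(self):
        return self.segments[0][0], self.segments[-1][1]


def _merge_lineages(x: _Lineage, y: _Lineage, full: int):
    """Coalesce two lineages; drop fully coalesced material (MRCA rule)."""
    cuts = sorted({a for seg in (x.segments + y.segments) for a in seg[:2]})
    out = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        m = 0
        for segs in (x.segments, y.segments):
            for sa, sb, sm in segs:
                if sa <= a and b <= sb:
                    m |= sm
        if m and m != full:
            if out and out[-1][1] == a and out[-1][2] == m:
                out[-1] = (out[-1][0], b, m)
            else:
                out.append((a, b, m))
    return _Lineage(out) if out else None


def _simulate_builtin(spec: SimSpec, return_truth: bool):
    rng = np.random.default_rng(spec.seed)
    n, l = spec.n, spec.l
    theta = 4.0 * spec.Ne * spec.mu_prime * l
    rho = 4.0 * spec.Ne * spec.rho * l
    harmonic = sum(1.0 / k for k in range(1, n))
    expected = n + (theta + rho) * harmonic
    if expected > _MAX_EVENTS:
        raise RuntimeError(
            f"about {expected:.0f} events expected, beyond the supported "
            f"event budget of {_MAX_EVENTS}; reduce n, l or the rates, or "
            "use the msprime engine")
    full = (1 << n) - 1
    lineages = [_Lineage([(0.0, l, 1 << i)]) for i in range(n)]
    muts: list[tuple[float, int]] = []  # (position, leafmask)
    n_recomb = 0
    events = 0
    while lineages:
        events += 1
        if events > _MAX_EVENTS:
            raise RuntimeError(
                "simulation exceeds the supported event budget; "
                "reduce n, l or the rates")
        k = len(lineages)
        coal_rate = k * (k - 1) / 2.0
        spans = [x.span() for x in lineages]
        rec_rates = [(rho / 2.0) * (b - a) / l for a, b in spans]
        measures = [x.measure() for x in lineages]
        mut_rate = (theta / 2.0) * sum(measures) / l
        total = coal_rate + sum(rec_rates) + mut_rate
        u = rng.uniform(0.0, total)
        if u < coal_rate:
            i, j = rng.choice(k, size=2, replace=False)
            merged = _merge_lineages(lineages[i], lineages[j], full)
            for idx in sorted((int(i), int(j)), reverse=True):
                lineages.pop(idx)
            if merged is not None:
                lineages.append(merged)
        elif u < coal_rate + sum(rec_rates):
            i = int(rng.choice(k, p=np.array(rec_rates) / sum(rec_rates)))
            a, b = spans[i]
            bp = rng.uniform(a, b)
            left = [s for s in lineages[i].segments if s[0] < bp]
            right = [s for s in lineages[i].segments if s[1] > bp]
            left = [(sa, min(sb, bp), m) for sa, sb, m in left]
            right = [(max(sa, bp), sb, m) for sa, sb, m in right]
            if left and right:
                n_recomb += 1
                lineages[i] = _Lineage(left)
                lineages.append(_Lineage(right))
        else:
            i = int(rng.choice(k, p=np.array(measures) / sum(measures)))
            target = rng.uniform(0.0, measures[i])
            acc = 0.0
            for sa, sb, m in lineages[i].segments:
                if acc + (sb - sa) >= target:
                    muts.append((sa + (target - acc), m))
                    break
                acc += sb - sa
    muts.sort()
    positions = [p for p, _ in muts]
    matrix = np.zeros((len(muts), n), dtype=np.int8)
    for row, (_, m) in enumerate(muts):
        for j in range(n):
            if m >> j & 1:
                matrix[row, j] = 1
    sample = _to_sample(matrix, positions, spec)
    info = {"n_recombination_events": n_recomb, "n_mutations": len(muts)}
    return (sample, info) if return_truth else sample


# ---------------------------------------------------------------------------
# ADH-scale fixture


def synthetic_kreitman_scale_sample() -> Sample:
    """A SYNTHETIC stand-in for the classic 11-haplotype ADH sample.

    This is *not* the real Kreitman alcohol-dehydrogenase data: it is a
    deterministic coalescent draw shaped to the same scale -- 11 haplotypes,
    43 biallelic segregating sites over a 4750 bp locus -- with a
    Drosophila-like recombination-to-mutation ratio.  The returned sample
    carries the analysis parameters used for D. melanogaster ADH studies
    (per-site mutation rate 5.49e-9, Ne = 1,720,600), which drive the global
    mutation rate of the tree-building weights.
    """
    n, l = 11, 4750.0
    mu_prime, ne_analysis = 5.49e-9, 1_720_600.0
    # simulation effective size chosen so E[#segregating sites] ~ 43
    ne_sim = 43 / (sum(1.0 / k for k in range(1, n)) * 4 * mu_prime * l)
    spec = SimSpec(n=n, l=l, Ne=ne_sim, mu_prime=mu_prime, rho=2.4e-8,
                   seed=_ADH_SEED)
    base = simulate_sample(spec, engine="msprime")
    return Sample(base.sequences, base.positions, l, mu_prime, ne_analysis)


# Internal seed fixed so the stand-in has exactly 43 segregating sites.
_ADH_SEED = 2
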