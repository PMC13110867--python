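# Methods

This note records the model implemented by `argsweep`, the numerical and
design choices made where the design was genuinely open, what the
synthetic-data generators do and do not emulate, and the known
limitations.  Units: genomic positions and interval endpoints are base
pairs in half-open `[a, b)` form, 0-based; latitudes (vertex times) are in
coalescent units of `2 Ne` generations, rescaled to generations only at
tree-sequence export; marker indices are 0-based internally and 1-based in
every user-facing report.

## Haplotypes and consistency

Haplotypes are vectors over GF(2) (0 = wild/ancestral, 1 = derived),
packed LSB-first into 64-bit words.  XOR of parent and child haplotypes,
AND-masked to an edge's ancestral material, marks the markers mutating on
that edge; the scanner processes markers in chunks (default 8, a package
constant configurable per call; correctness never depends on it) and may
skip any edge whose child chunk is all-zero, because a parent's allele is
the AND of its material-carrying children and 0 is absorbing.

One semantic point deserves emphasis: a coalescence vertex's allele at a
marker is the AND of the alleles of *those children whose edge carries the
marker*.  A child contributing no material there is neutral (a marker
carried by nobody defaults to 1, a value nothing ever consults).
Recombination vertices reference their only child's haplotype.  Under this
masked rule, a marker's mutation edges are exactly the allele flips along
its marginal tree, and the wild-event cascade (below) behaves as the
candidate analysis requires.  A plain AND over all graph descendants would
pin alleles to lineages that no longer carry the marker and block wild
events entirely.

A genealogy is *consistent* when every marker has at most one mutation
edge.  `validate()` checks structure — degrees, strict latitude increase
along edges, the interval rule (parental ancestral material = mask
intersected with the union of the child edges' material), mask partitions,
the counting identity `#coalescences = #recombinations + n - 1`, and the
masked-AND haplotype rule — and reports structural corruption separately
from mere inconsistency.

## Tree construction

Partner weights are `p_ab = mu^{d_ab} / Gamma(d_ab + 1)` with
`d_ab = c0 * d(h_a, h_b)` and `mu = 4 Ne mu' l`.  `log Gamma` is the
library log-gamma, not a literal Stirling expansion — strictly more
accurate with the same asymptotics.  Categorical sampling is Gumbel-max;
the secretary variant observes `ceil(t0 m)` candidates (in a fresh uniform
random order each event, which the secretary analysis requires), then
returns at the first candidate beating the record, falling back to the
full argmax.  This scheme reproduces both closed forms: early-termination
probability `1 - t0` and success probability `t0 (1 - log t0)` as the
candidate count grows.

Latitude increments are `Exp(#live vertices)` — the model's stated rate,
not the standard coalescent's `k(k-1)/2` — so the mean tree height is
`sum_{k=2}^n 1/k` and the height property tests use that form.  The tree
log-density sums, per event, the exponential increment density and the
chosen partner's log-weight minus the log-sum-exp of the traversed
weights (all candidates when `t0 = 1`, the traversed prefix otherwise).

Degenerate weights: with a hard bias (`c0 = inf`) every candidate of the
drawn first partner can have weight zero (a singleton allele class).  The
builder then redraws the first partner uniformly among vertices that have
at least one positive-weight mate, and only forces a uniform pairing when
no such pair exists (the final cross-class join).  Without this rule,
trees consistent with the first marker would be unreachable whenever an
allele class is a singleton.

## The sweep

At the focal marker `m` with mutation-edge set `M` (|M| >= 2):

* **Derived candidates** are each mutation edge plus the chain of
  marginally siblingless edges below it; extracting any of them removes
  that mutation.  **Wild candidates** are the edges of a wild branch whose
  marginal brother and uncle are both mutation branches; extraction merges
  the brother with the uncle and the reduction can cascade through
  further "derived cousins".  Candidates are pooled and drawn with
  probability proportional to branch length, with no priority between
  kinds.
* **Removal effects.** Withdrawing wild material flips the alleles of the
  contiguous run of upstream vertices whose remaining carriers are all
  derived (withdrawing derived material never changes an allele).  This
  *removal-affected* set is computed before the event and used twice:
  recoalescence targets whose merge vertex lies in it are rejected, and
  the breakpoint admissibility conditions consult it marker by marker.
  Ignoring it produces events that fail to reduce the mutation count
  (caught by the strict-decrease guard during development).
* **Recoalescence.** A derived lineage may join any edge whose first
  material-carrying vertex upstream is derived, excluding the extraction
  path; edges are weighted by their length above the recombination
  latitude and the location is Beta(2,2) on the admissible portion.  A
  wild lineage joins wild-leading edges; its latitude is the first event
  of an inhomogeneous Poisson process whose intensity is the number of
  admissible edges alive at each latitude, integrated on a logarithmic
  grid (default 25 nodes, piecewise-constant from one pass over edge
  spans; in the homogeneous limit the draw is exactly exponential) and
  extended above the root at constant rate 1, where recoalescence promotes
  a fresh gMRCA.
* **Sterile candidates.** A derived candidate whose admissible targets all
  die out below every latitude on its own span cannot recoalesce; the
  recombination latitude is first redrawn under the admissible cap, and if
  none exists the candidate is dropped from the pool and the
  length-weighted draw repeated.  An above-root fallback is pointless for
  derived lineages: it replaces the extracted mutation edge with a new one
  on the freed lineage, leaving the count unchanged.
* **Breakpoints** are uniform on `[b', m)`; the lower bound scans markers
  leftward and stops at the first marker where the moved material would
  create a mutation (the recombining edge carries the marker, and the
  recoalescence side neither matches alleles directly nor via its first
  carrier upstream, affected-set overrides applied).  Draws avoid exact
  marker positions and interval endpoints, and the bound never goes below
  the leftmost point of the recombining edge's material (discarding
  type-4 outcomes).  Each event must strictly decrease the focal count —
  an assertion aborts with diagnostics otherwise — bounding the work per
  marker by `|M| - 1` events.
* **MCO.** When the drawn candidate is a parental edge of an existing
  recombination vertex whose mask side owns the genome tail, and routing
  the moved material through the other parental edge merges it admissibly,
  the masks are edited in place (tail side clipped to `[0, b')`, the other
  side gaining `[b', inf)`) and no vertices are added.  No extra bias
  toward MCO events is applied.
* **Window.** A width-`w` window centered on the event position excludes
  candidate recombination and recoalescence edges (and their contribution
  to recoalescence rates) whose material misses `[p - w, p + w]`; `w = 0`
  approximates an SMC-like first-order Markov process, `w = inf` is
  exact.  The filter is not applied above the root, where the unit rate is
  kept.  Mutation edges always contain the focal position, so progress is
  guaranteed at any width.

Upstream repair after each event walks parents in latitude order,
recomputing haplotypes and ancestral intervals, and stops through any edge
whose (haplotype, interval) pair hashes unchanged — an NH-family 64-bit
universal hash over 32-bit lanes, keyed from the run seed so a collision,
if one ever occurred, would be reproducible; `validate()` is the terminal
safety net.  Marker/position conversion uses the least-squares-seeded
interpolation-sequential search over the (immutable) position vector, with
0 as the sentinel for "no marker at or left of p".

## Synthetic data

`simulate_sample` prefers msprime (standard coalescent, binary
infinite-sites mutations on a continuous genome, diploid scaling
`theta = 4 Ne mu' l`).  The built-in engine is an independent Hudson
coalescent with recombination: lineages carry (segment, leaf-set) lists,
fully coalesced material is dropped, coalescence at rate `k(k-1)/2`,
per-lineage recombination at `rho/2` times the closure span fraction, and
mutations as point events on ancestral material.  Both engines satisfy
Watterson's `E[S] = theta * sum 1/k` and `E[pi] = theta`, which the tests
check; the builtin refuses parameter combinations implying more than 1e5
events.  These generators emulate neutral, panmictic, constant-size
populations with fully phased, polarized, error-free haplotypes; they do
not emulate selection, demography, gene conversion, genotyping error or
polarization error, so passing tests speak to algorithmic correctness
under the model, not robustness to real-data artifacts.

The ADH-scale fixture (`synthetic_kreitman_scale_sample`) is a **synthetic
stand-in** for the classic 11-haplotype, 43-site alcohol-dehydrogenase
sample: a fixed-seed coalescent draw at that exact scale (4750 bp,
per-site mutation rate 5.49e-9, a Drosophila-like recombination-to-
mutation ratio of ~4.4, simulation population size chosen so the expected
number of segregating sites is 43).  Real ADH haplotypes are not bundled.
The recombination-count experiment treats the locus as a unit-length
segment, so the global rate entering the pairing weights is
`mu = 4 Ne mu' ~ 0.038` with the stated analysis parameters
(`Ne = 1,720,600`); keeping `mu < 1` makes the Poisson weight decrease
with distance, and the Hamming-built trees then yield more parsimonious
ancestries than left-marker trees, the qualitative ordering such studies
report.  With `l` in bp the rate would be ~179 and the weight would
*increase* over the observable distance range, inverting that ordering.
Measured on the stand-in (which is not the real data), mean counts are
near 26 with SD near 3; counts on other datasets of this size will differ
with the four-gamete structure of the data.

## Problem sizes

Default test and acceptance runs use sizes chosen to exercise every code
path at small scale: fuzz samples up to n = 20 haplotypes and ~50 markers,
200-replicate consistency and window studies, 2000-replicate height
checks, and a few thousand replicates per metric for the ADH experiment.
All statistical assertions use 4-sigma bands or chi-square/KS tests at
conservative thresholds.

## Known limitations

* Markers must be biallelic, polarized, fully phased and fully observed;
  missing data and multiallelic sites are rejected at input.
* The event distributions are restricted relative to the coalescent with
  recombination exactly as described above (supports shrunk to enforce
  consistency; sterile candidates excluded); the sampler is not an exact
  CWR posterior.
* Inference is single-threaded by design; parallelism is expected to come
  from independent replicate runs.
* MCO detection is deliberately conservative (tail-owning sides only, no
  bias toward reuse), so such events are rare.
* The builtin Hudson engine targets fixture scales (<= ~1e5 events), not
  genome-scale simulation; use msprime beyond that.
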