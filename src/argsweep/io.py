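"""VCF ingestion and tree-sequence interchange.

Input is restricted to phased, polarized, biallelic variation: the REF
allele is taken to be ancestral (wild, 0) and the single ALT derived (1).
Each phased diploid sample contributes two independent haplotypes.  VCF
``POS`` is 1-based; internal coordinates are 0-based half-open, converted at
this boundary only.

Consistent genealogies can be exported as tskit tables: node times are
latitudes rescaled to generations (times 2 Ne), edges carry one row per
maximal ancestral interval, and each marker contributes one site with its
unique mutation edge (or a root mutation when the derived allele has fixed
in the sample).
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .bitseq import Sample, Sequence
from .genealogy import Genealogy, is_consistent

__all__ = ["read_vcf", "write_vcf", "to_tree_sequence", "from_tree_sequence"]

log = logging.getLogger(__name__)


def read_vcf(path: str, *, seq_length: float | None = None,
             mu_prime: float = 1e-8, Ne: float = 1e4) -> Sample:
    """Read phased, biallelic, fully called genotypes into a Sample.

    Non-biallelic records are skipped (counted and logged); an unphased or
    missing genotype is an error naming the offending record.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    haplotypes: list[list[int]] = []
    positions: list[float] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        row: list[int] = []
        for geno in var.genotypes:
            *alleles, phased = geno
            if any(a < 0 for a in alleles):
                raise ValueError(
                    f"missing genotype at {var.CHROM}:{var.POS}; "
                    "missing data is not supported")
            if len(alleles) > 1 and not phased:
                raise ValueError(f"unphased genotype at {var.CHROM}:{var.POS}")
            if any(a > 1 for a in alleles):
                raise ValueError(f"non-biallelic call at {var.CHROM}:{var.POS}")
            row.extend(alleles)
        if not haplotypes:
            haplotypes = [[] for _ in row]
        for h, a in zip(haplotypes, row):
            h.append(a)
        positions.append(float(var.POS - 1))
    if n_skipped:
        log.warning("skipped %d non-biallelic records", n_skipped)
    if not positions:
        raise ValueError("no usable biallelic records in VCF")
    if seq_length is None:
        seq_length = positions[-1] + 1.0
    seqs = [Sequence.from_bits(h) for h in haplotypes]
    return Sample(seqs, positions, seq_length, mu_prime, Ne)


def write_vcf(sample: Sample, path: str, *, chrom: str = "1") -> None:
    """Write a sample as a plain-text phased VCF (pairs of haplotypes form
    diploid samples; a trailing unpaired haplotype is written haploid)."""
    n = sample.n
    n_dip = n // 2
    names = [f"sample{i}" for i in range(n_dip)] + (
        ["sampleH"] if n % 2 else [])
    with open(path, "w") as f:
        f.write("##fileformat=VCFv4.2\n")
        f.write(f"##contig=<ID={chrom},length={int(sample.seq_length)}>\n")
        f.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        f.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(names) + "\n")
        for k in range(sample.s):
            pos = int(sample.positions[k]) + 1
            gts = []
            for i in range(n_dip):
                a = sample.sequences[2 * i].bit(k)
                b = sample.sequences[2 * i + 1].bit(k)
                gts.append(f"{a}|{b}")
            if n % 2:
                gts.append(str(sample.sequences[-1].bit(k)))
            f.write(f"{chrom}\t{pos}\t.\tA\tT\t.\tPASS\t.\tGT\t"
                    + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# Tree sequences


def to_tree_sequence(g: Genealogy):
    """Export a consistent genealogy as a tskit TreeSequence."""
    import tskit

    ok, counts = is_consistent(g)
    if not ok:
        raise ValueError(
            "genealogy is not consistent with its sample; refusing to export "
            "(the infinite-sites contract is one mutation per site)")
    l = g.sample.seq_length
    scale = 2.0 * g.sample.Ne
    tables = tskit.TableCollection(sequence_length=l)
    for v in range(g.n_vertices):
        flags = tskit.NODE_IS_SAMPLE if v < g.n_leaves else 0
        tables.nodes.add_row(flags=flags, time=g.latitude[v] * scale)
    for e in g.iter_edges():
        for a, b in e.ancestral:
            a, b = max(a, 0.0), min(b, l)
            if a < b:
                tables.edges.add_row(left=a, right=b, parent=e.parent,
                                     child=e.child)
    for k in range(g.sample.s):
        site = tables.sites.add_row(position=float(g.sample.positions[k]),
                                    ancestral_state="0")
        edges = g.mutation_edges_at(k)
        if edges:
            node = edges[0].child
        elif all(h.bit(k) for h in g.sample.sequences):
            node = g.root  # derived allele fixed in the sample
        else:
            continue  # monomorphic wild: no mutation
        tables.mutations.add_row(site=site, node=node, derived_state="1")
    tables.sort()
    return tables.tree_sequence()


def from_tree_sequence(ts, *, mu_prime: float = 1e-8,
                       Ne: float = 1e4) -> Sample:
    """Build a Sample from a tskit tree sequence with binary variants."""
    positions, columns = [], []
    for var in ts.variants():
        geno = np.asarray(var.genotypes)
        if geno.min() < 0 or len(var.alleles) - (None in var.alleles) > 2:
            raise ValueError("only fully called biallelic variants supported")
        geno = (geno > 0).astype(np.int8)
        if geno.min() == geno.max():
            continue
        positions.append(var.site.position)
        columns.append(geno)
    matrix = np.array(columns, dtype=np.int8)
    seqs = [Sequence.from_bits(matrix[:, j]) for j in range(matrix.shape[1])]
    return Sample(seqs, positions, ts.sequence_length, mu_prime, Ne)
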