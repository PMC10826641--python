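"""Shared fixtures: hand-built matrices, toy VCFs and naive oracles."""

from __future__ import annotations

import numpy as np
import pytest

from introscape.core import MISSING, GenotypeMatrix, PopulationMap


def make_matrix(
    genotypes,
    positions=None,
    scaffold="s1",
    sample_ids=None,
    ref=None,
    alt=None,
) -> GenotypeMatrix:
    """GenotypeMatrix from a plain nested list (one scaffold)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1)
    if sample_ids is None:
        sample_ids = [f"smp{j + 1}" for j in range(n_samples)]
    return GenotypeMatrix(
        scaffold_names=[scaffold],
        scaffold_index=np.zeros(n_sites, dtype=np.int32),
        positions=np.asarray(positions, dtype=np.int64),
        genotypes=g,
        ref=np.array(ref if ref is not None else ["A"] * n_sites),
        alt=np.array(alt if alt is not None else ["C"] * n_sites),
        sample_ids=list(sample_ids),
    )


def naive_pi(genotypes, cols) -> tuple[int, int]:
    """All-pairs allele-comparison oracle for pi: (diffs, comparisons).

    Enumerates every unordered pair of non-missing alleles explicitly.
    """
    diffs = comps = 0
    for row in genotypes:
        alleles = []
        for j in cols:
            g = row[j]
            if g == MISSING:
                continue
            alleles += [1] * g + [0] * (2 - g)
        for i in range(len(alleles)):
            for k in range(i + 1, len(alleles)):
                comps += 1
                diffs += alleles[i] != alleles[k]
    return diffs, comps


def naive_dxy(genotypes, cols_a, cols_b) -> tuple[int, int]:
    """All cross-population allele pairs, enumerated explicitly."""
    diffs = comps = 0
    for row in genotypes:
        def alleles(cols):
            out = []
            for j in cols:
                g = row[j]
                if g == MISSING:
                    continue
                out += [1] * g + [0] * (2 - g)
            return out

        for a in alleles(cols_a):
            for b in alleles(cols_b):
                comps += 1
                diffs += a != b
    return diffs, comps


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID={contig},length={length}>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_vcf_text(path, records, samples, contig="s1", length=1_000_000):
    """Write a toy VCF; *records* are pre-formatted data lines."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(contig=contig, length=length, samples="\t".join(samples)))
        for rec in records:
            fh.write(rec + "\n")
    return path


@pytest.fixture
def popmap_two_pops():
    return PopulationMap(
        {"smp1": "A", "smp2": "A", "smp3": "B", "smp4": "B"}
    )
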