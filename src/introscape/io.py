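"""Readers/writers for VCF, GFF3/BED, Newick and consensus FASTA.

VCF parsing goes through pysam; the soft filters applied while reading
follow the resequencing-study convention for an "all sites" callset:

* a variant site failing the site-quality threshold is *converted to an
  invariant reference site* (all genotypes set to 0) rather than dropped;
* depth failures (site total depth outside bounds, or per-genotype depth
  below the minimum) produce missing data;
* a site whose missing-genotype fraction exceeds the cap is dropped;
* non-biallelic and non-SNP records are dropped.

Filter order is quality -> depth -> missingness, and the whole procedure
is idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pysam
import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    MISSING,
    FormatError,
    GenotypeMatrix,
    IntervalSet,
    ValidationError,
    merge_intervals,
)

logger = logging.getLogger(__name__)

# Unordered genotype -> IUPAC ambiguity code.
IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


@dataclass
class FilterConfig:
    """Soft-filter thresholds for building a genotype matrix from a VCF.

    ``min_site_quality`` acts on the record QUAL field (site level); set
    ``min_genotype_quality`` to additionally mask genotypes on FORMAT/GQ.
    A threshold of ``None`` disables that filter.
    """

    min_site_quality: float | None = 20.0
    min_site_depth: int | None = 3
    max_site_depth: int | None = 60
    min_genotype_depth: int | None = 2
    max_site_missingness: float = 0.5
    min_genotype_quality: float | None = None

    def __post_init__(self) -> None:
        if (
            self.min_site_depth is not None
            and self.max_site_depth is not None
            and self.min_site_depth > self.max_site_depth
        ):
            raise ValidationError("min_site_depth > max_site_depth")
        if not 0.0 <= self.max_site_missingness <= 1.0:
            raise ValidationError("max_site_missingness must be in [0, 1]")

    @classmethod
    def permissive(cls) -> "FilterConfig":
        """No-op filters (used for round-tripping simulated data)."""
        return cls(
            min_site_quality=None,
            min_site_depth=None,
            max_site_depth=None,
            min_genotype_depth=None,
            max_site_missingness=1.0,
        )


@dataclass
class FilterStats:
    """Bookkeeping of records touched by each filter, for the run log."""

    n_records: int = 0
    n_non_biallelic_dropped: int = 0
    n_non_snp_dropped: int = 0
    n_qual_converted: int = 0
    n_site_depth_masked: int = 0
    n_genotypes_depth_masked: int = 0
    n_genotypes_gq_masked: int = 0
    n_missingness_dropped: int = 0
    n_retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


_BASES = {"A", "C", "G", "T"}


def read_vcf(path, filters: FilterConfig | None = None):
    """Read a VCF into a :class:`GenotypeMatrix`, applying soft filters.

    Returns ``(matrix, stats)`` where *stats* is a :class:`FilterStats`
    accounting for every input record.  Both variant and invariant sites
    are retained (invariant sites carry ``alt == '.'``); downstream
    diversity denominators rely on the invariant sites of an "all sites"
    callset.
    """
    if filters is None:
        filters = FilterConfig()
    stats = FilterStats()
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read VCF {path}: {exc}") from exc

    samples = list(vf.header.samples)
    n_samples = len(samples)
    scaffold_names: list[str] = []
    scaf_idx: list[int] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    warned_depth = False

    for rec in vf:
        stats.n_records += 1
        if len(rec.samples) != n_samples:
            raise FormatError(
                f"{path}: record at {rec.chrom}:{rec.pos} has "
                f"{len(rec.samples)} samples, header has {n_samples}"
            )
        rec_alts = [a for a in (rec.alts or []) if a != "<NON_REF>"]
        if len(rec_alts) > 1:
            stats.n_non_biallelic_dropped += 1
            continue
        ref = (rec.ref or "N").upper()
        alt = rec_alts[0].upper() if rec_alts else "."
        if ref not in _BASES or (alt != "." and alt not in _BASES):
            stats.n_non_snp_dropped += 1
            continue

        row = np.full(n_samples, MISSING, dtype=np.int8)
        gt_depths = np.full(n_samples, -1, dtype=np.int64)
        gt_quals = np.full(n_samples, np.inf)
        for j, name in enumerate(samples):
            call = rec.samples[name]
            gt = call.get("GT")
            if gt is not None and all(a is not None for a in gt):
                row[j] = sum(1 for a in gt if a != 0)
            dp = call.get("DP")
            if dp is None:
                ad = call.get("AD")
                if ad is not None:
                    dp = sum(a for a in ad if a is not None)
            if dp is not None:
                gt_depths[j] = dp
            gq = call.get("GQ")
            if gq is not None:
                gt_quals[j] = gq

        # 1. site quality: failing sites become invariant reference.
        if filters.min_site_quality is not None and rec.qual is not None:
            if rec.qual < filters.min_site_quality and alt != ".":
                row[:] = 0
                alt = "."
                stats.n_qual_converted += 1

        # 2. depth filters -> missing data.
        have_depth = (gt_depths >= 0).any()
        if not have_depth and (
            filters.min_site_depth is not None
            or filters.min_genotype_depth is not None
        ):
            if not warned_depth:
                logger.warning(
                    "%s: no per-genotype depth (DP/AD); depth filters skipped", path
                )
                warned_depth = True
        elif have_depth:
            site_dp = int(gt_depths[gt_depths >= 0].sum())
            if (
                filters.min_site_depth is not None
                and site_dp < filters.min_site_depth
            ) or (
                filters.max_site_depth is not None
                and site_dp > filters.max_site_depth
            ):
                row[:] = MISSING
                stats.n_site_depth_masked += 1
            elif filters.min_genotype_depth is not None:
                low = (gt_depths >= 0) & (gt_depths < filters.min_genotype_depth)
                stats.n_genotypes_depth_masked += int((low & (row != MISSING)).sum())
                row[low] = MISSING
        if filters.min_genotype_quality is not None:
            lowq = gt_quals < filters.min_genotype_quality
            stats.n_genotypes_gq_masked += int((lowq & (row != MISSING)).sum())
            row[lowq] = MISSING

        # 3. missingness -> drop site.
        if (row == MISSING).mean() > filters.max_site_missingness:
            stats.n_missingness_dropped += 1
            continue

        if rec.chrom not in scaffold_names:
            scaffold_names.append(rec.chrom)
        scaf_idx.append(scaffold_names.index(rec.chrom))
        positions.append(rec.pos)
        refs.append(ref)
        alts.append(alt)
        rows.append(row)
        stats.n_retained += 1

    matrix = GenotypeMatrix(
        scaffold_names=scaffold_names,
        scaffold_index=np.array(scaf_idx, dtype=np.int32),
        positions=np.array(positions, dtype=np.int64),
        genotypes=(
            np.vstack(rows) if rows else np.empty((0, n_samples), dtype=np.int8)
        ),
        ref=np.array(refs, dtype="U1"),
        alt=np.array(alts, dtype="U1"),
        sample_ids=samples,
    )
    return matrix, stats


def write_vcf(matrix: GenotypeMatrix, path, scaffold_lengths: dict[str, int] | None = None) -> None:
    """Write a GenotypeMatrix as a minimal GT-only VCF (v4.2, unphased)."""
    if scaffold_lengths is None:
        scaffold_lengths = {}
        for i, name in enumerate(matrix.scaffold_names):
            mask = matrix.scaffold_index == i
            scaffold_lengths[name] = int(matrix.positions[mask].max()) if mask.any() else 1
    gt_strings = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=introscape\n")
        for name in matrix.scaffold_names:
            fh.write(f"##contig=<ID={name},length={scaffold_lengths[name]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for i in range(matrix.n_sites):
            gts = "\t".join(gt_strings[int(g)] for g in matrix.genotypes[i])
            fh.write(
                f"{matrix.scaffold_of(i)}\t{matrix.positions[i]}\t.\t"
                f"{matrix.ref[i]}\t{matrix.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_intervals(path, dialect: str | None = None) -> dict[str, IntervalSet]:
    """Read CDS intervals from GFF3 or BED into merged per-scaffold sets.

    GFF3 rows are filtered to feature type ``CDS`` and converted from
    1-based closed to 0-based half-open coordinates; BED is used as is.
    The dialect is inferred from the extension when not given.
    """
    path = str(path)
    if dialect is None:
        low = path.lower()
        dialect = "GFF3" if low.endswith((".gff", ".gff3")) else "BED"
    dialect = dialect.upper()
    if dialect not in {"GFF3", "BED"}:
        raise ValidationError(f"unknown interval dialect {dialect!r}")

    raw: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if dialect == "GFF3":
                if len(cols) < 5:
                    raise FormatError(f"{path}:{lineno}: expected >=5 GFF3 columns")
                if cols[2] != "CDS":
                    continue
                scaffold = cols[0]
                start, end = int(cols[3]) - 1, int(cols[4])
            else:
                if len(cols) < 3:
                    raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
                scaffold = cols[0]
                start, end = int(cols[1]), int(cols[2])
            if end <= start:
                raise FormatError(f"{path}:{lineno}: empty interval ({start}, {end})")
            raw.setdefault(scaffold, []).append((start, end))
    return {
        scaffold: IntervalSet(scaffold=scaffold, intervals=merge_intervals(ivs))
        for scaffold, ivs in raw.items()
    }


def read_trees(path) -> list[dendropy.Tree]:
    """Read one Newick tree per line (blank lines skipped)."""
    trees: list[dendropy.Tree] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                tree = dendropy.Tree.get(
                    data=line,
                    schema="newick",
                    preserve_underscores=True,
                    suppress_internal_node_taxa=True,
                )
            except Exception as exc:
                raise FormatError(f"{path}:{lineno}: cannot parse newick: {exc}") from exc
            trees.append(tree)
    return trees


def write_trees(trees, path) -> None:
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(
                tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n"
            )


def consensus_sequence(matrix: GenotypeMatrix, reference: str, scaffold: str, sample: str) -> str:
    """Apply one sample's genotypes to a reference scaffold sequence.

    Heterozygotes become IUPAC ambiguity codes, missing genotypes become N.
    """
    if sample not in matrix.sample_ids:
        raise ValidationError(f"unknown sample {sample!r}")
    col = matrix.sample_ids.index(sample)
    seq = list(reference.upper())
    s = matrix.scaffold_names.index(scaffold)
    for i in np.nonzero(matrix.scaffold_index == s)[0]:
        pos0 = int(matrix.positions[i]) - 1
        if pos0 >= len(seq):
            raise ValidationError(
                f"site {scaffold}:{matrix.positions[i]} beyond reference "
                f"length {len(seq)}"
            )
        g = int(matrix.genotypes[i, col])
        ref, alt = str(matrix.ref[i]), str(matrix.alt[i])
        if g == MISSING:
            seq[pos0] = "N"
        elif g == 0 or alt == ".":
            seq[pos0] = ref
        elif g == 2:
            seq[pos0] = alt
        else:
            seq[pos0] = IUPAC[frozenset({ref, alt})]
    return "".join(seq)


def write_consensus_fasta(matrix: GenotypeMatrix, reference: dict[str, str], sample: str, path=None):
    """Consensus records for one sample over all reference scaffolds.

    ``reference`` maps scaffold name to sequence (e.g. from
    ``Bio.SeqIO``).  Writes FASTA to *path* when given; always returns
    the list of SeqRecords.
    """
    records = []
    for scaffold in matrix.scaffold_names:
        if scaffold not in reference:
            raise ValidationError(f"reference lacks scaffold {scaffold!r}")
        seq = consensus_sequence(matrix, reference[scaffold], scaffold, sample)
        records.append(
            SeqRecord(Seq(seq), id=f"{sample}|{scaffold}", description="")
        )
    if path is not None:
        SeqIO.write(records, str(path), "fasta")
    return records


def read_fasta(path) -> dict[str, str]:
    """FASTA file as an ordered name -> sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
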