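"""Core in-memory containers shared by every stage of the pipeline.

The central object is :class:`GenotypeMatrix`, a site x sample table of
diploid alternate-allele counts over one or more scaffolds.  All window
statistics (pi, dxy, FST, D, f4-ratio, f_dM) are computed from population
allele frequencies derived from this matrix, so it stores the minimum
needed to do that under missing data: positions, per-site alleles and an
integer genotype code (0, 1, 2 alternate alleles, or MISSING).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel genotype value for a missing diploid call.
MISSING: int = -1


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class FormatError(ValueError):
    """Raised for malformed records in an input file."""


@dataclass
class GenotypeMatrix:
    """Biallelic site x sample diploid genotype table.

    Parameters
    ----------
    scaffold_names
        Ordered scaffold names; ``scaffold_index`` points into this list.
    scaffold_index
        Per-site scaffold index (int array, length ``n_sites``), grouped so
        that all sites of a scaffold are contiguous.
    positions
        Per-site 1-based coordinates, strictly increasing within a scaffold.
    genotypes
        ``(n_sites, n_samples)`` int8 array of alternate-allele counts in
        {0, 1, 2} or :data:`MISSING`.
    ref, alt
        Per-site reference/alternate bases.  Invariant (monomorphic
        reference) sites carry ``alt == '.'``.
    sample_ids
        Ordered sample names matching genotype columns.
    """

    scaffold_names: list[str]
    scaffold_index: np.ndarray
    positions: np.ndarray
    genotypes: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.scaffold_index = np.asarray(self.scaffold_index, dtype=np.int32)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.ref = np.asarray(self.ref)
        self.alt = np.asarray(self.alt)
        self.validate()

    # -- invariants -----------------------------------------------------

    def validate(self) -> None:
        n = self.n_sites
        if self.genotypes.shape != (n, self.n_samples):
            raise ValidationError(
                f"genotypes shape {self.genotypes.shape} does not match "
                f"{n} sites x {len(self.sample_ids)} samples"
            )
        if len(self.positions) != n or len(self.ref) != n or len(self.alt) != n:
            raise ValidationError("per-site arrays have inconsistent lengths")
        ok = (self.genotypes == MISSING) | (
            (self.genotypes >= 0) & (self.genotypes <= 2)
        )
        if not ok.all():
            raise ValidationError("genotype codes must be 0, 1, 2 or MISSING")
        for s in np.unique(self.scaffold_index):
            pos = self.positions[self.scaffold_index == s]
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise ValidationError(
                    f"positions not strictly increasing on scaffold "
                    f"{self.scaffold_names[int(s)]}"
                )

    # -- basic queries --------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def scaffold_of(self, i: int) -> str:
        return self.scaffold_names[int(self.scaffold_index[i])]

    def is_variant(self) -> np.ndarray:
        """Boolean mask of sites segregating among the non-missing calls."""
        g = np.where(self.genotypes == MISSING, np.int16(0), self.genotypes.astype(np.int16))
        present = self.genotypes != MISSING
        alt_sum = (g * present).sum(axis=1)
        n_alleles = 2 * present.sum(axis=1)
        return (alt_sum > 0) & (alt_sum < n_alleles)

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given site indices (order preserved)."""
        return GenotypeMatrix(
            scaffold_names=list(self.scaffold_names),
            scaffold_index=self.scaffold_index[index],
            positions=self.positions[index],
            genotypes=self.genotypes[index],
            ref=self.ref[index],
            alt=self.alt[index],
            sample_ids=list(self.sample_ids),
        )

    def sites_in_window(self, scaffold: str, start: int, end: int) -> np.ndarray:
        """Indices of sites with 0-based coordinate in ``[start, end)``."""
        s = self.scaffold_names.index(scaffold)
        mask = self.scaffold_index == s
        idx = np.nonzero(mask)[0]
        pos0 = self.positions[idx] - 1
        lo = np.searchsorted(pos0, start, side="left")
        hi = np.searchsorted(pos0, end, side="left")
        return idx[lo:hi]

    # -- allele frequencies ---------------------------------------------

    def allele_counts(self, columns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, non-missing allele count) over columns."""
        g = self.genotypes[:, columns]
        present = g != MISSING
        alt = np.where(present, g, 0).astype(np.int64).sum(axis=1)
        n = 2 * present.sum(axis=1).astype(np.int64)
        return alt, n


@dataclass
class PopulationMap:
    """Sample -> population assignment; defines P1/P2/P3/outgroup roles."""

    assignments: dict[str, str]

    @classmethod
    def from_tsv(cls, path) -> "PopulationMap":
        """Read a two-column TSV (sample, population); '#' lines ignored."""
        out: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) < 2:
                    raise FormatError(f"{path}:{lineno}: expected 'sample<TAB>population'")
                out[parts[0]] = parts[1]
        return cls(out)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for sample, pop in self.assignments.items():
                fh.write(f"{sample}\t{pop}\n")

    @property
    def populations(self) -> list[str]:
        seen: list[str] = []
        for p in self.assignments.values():
            if p not in seen:
                seen.append(p)
        return seen

    def samples(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    def column_indices(self, population: str, sample_ids: list[str]) -> np.ndarray:
        """Genotype-column indices of a population's samples in a matrix."""
        wanted = set(self.samples(population))
        if not wanted:
            raise ValidationError(f"unknown population {population!r}")
        cols = np.array([i for i, s in enumerate(sample_ids) if s in wanted], dtype=int)
        if len(cols) == 0:
            raise ValidationError(
                f"population {population!r} has no samples in the matrix"
            )
        return cols


@dataclass
class IntervalSet:
    """Merged, sorted 0-based half-open intervals on one scaffold."""

    scaffold: str
    intervals: list[tuple[int, int]]
    feature_type: str = "CDS"

    def __post_init__(self) -> None:
        self.intervals = merge_intervals(self.intervals)

    def total_length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def overlap(self, start: int, end: int) -> int:
        """Total overlap (bp) with window [start, end)."""
        total = 0
        for s, e in self.intervals:
            if s >= end:
                break
            total += max(0, min(e, end) - max(s, start))
        return total


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Sort and merge overlapping/abutting half-open intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    for s, e in ivs:
        if s < 0 or e <= s:
            raise ValidationError(f"bad interval ({s}, {e})")
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class Window:
    """A genomic window: bp-bounded, optionally tied to a SNP index range.

    ``start``/``end`` are 0-based half-open bp coordinates.  SNP-count
    windows additionally carry ``snp_start``/``snp_end``, indices into the
    matrix's variant-site list.  ``partial`` flags a terminal window
    shorter than the nominal size.
    """

    scaffold: str
    start: int
    end: int
    snp_start: int | None = None
    snp_end: int | None = None
    n_snps: int = 0
    genic_fraction: float | None = None
    partial: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"window start {self.start} >= end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def key(self) -> tuple[str, int, int]:
        return (self.scaffold, self.start, self.end)
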