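"""Loss-of-function scan of aligned CDS copies against a functional reference.

A copy is classified from three detectors run over a multiple alignment in
which the first row is a reference CDS known to translate cleanly:

* indels — maximal gap runs relative to the reference; deletions at or
  above a size threshold are "large deletions" (with the exons they
  remove), and any indel whose length is not a multiple of 3 is a
  frameshift;
* premature stops — the realized (gap-stripped) copy sequence is
  translated in the reference frame, and the first in-frame stop codon
  strictly upstream of the reference terminator is reported; IUPAC
  ambiguity codes are resolved into two haplotypes so a stop present on
  one allele only is reported as heterozygous;
* domain substitutions — nonsynonymous differences whose amino-acid
  position falls inside a named conserved domain (e.g. the heme-binding
  domain or a substrate recognition site of a cytochrome P450).

Verdicts: ``LOF`` for any large deletion / frameshift / premature stop,
``putative_reduced_function`` for domain substitutions only, ``intact``
otherwise.  In-frame indels and substitutions outside domains are
reported informationally and do not change the verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .core import ValidationError

# IUPAC ambiguity code -> sorted allele pair (single bases map to themselves)
AMBIG = {
    "A": "AA", "C": "CC", "G": "GG", "T": "TT",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "N": "NN", "-": "--",
}

LOF_KINDS = ("large_deletion", "frameshift", "premature_stop")


@dataclass
class LofEvent:
    kind: str
    position: int          # 0-based nucleotide coordinate in the reference CDS
    length: int = 0
    zygosity: str = "hom"  # hom | het | unknown
    exons: tuple[int, ...] = ()
    domain: str | None = None
    aa_position: int | None = None

    def identity(self) -> tuple:
        """Key for shared-mutation clustering across samples."""
        return (self.kind, self.position, self.length)


@dataclass
class LofReport:
    sample: str
    events: list[LofEvent]
    informational: list[LofEvent] = field(default_factory=list)

    @property
    def verdict(self) -> str:
        kinds = {e.kind for e in self.events}
        if kinds & set(LOF_KINDS):
            return "LOF"
        if kinds == {"domain_substitution"}:
            return "putative_reduced_function"
        if kinds:
            return "putative_reduced_function"
        return "intact"


@dataclass
class CdsAlignmentSet:
    """Aligned CDS copies against a functional reference.

    ``reference_row`` and every copy row have equal length; the reference
    row may carry gaps at insertion columns.  ``exon_boundaries`` are
    0-based half-open intervals in *reference CDS* coordinates;
    ``domains`` are named 0-based half-open amino-acid intervals.
    """

    reference_name: str
    reference_row: str
    copies: dict[str, str]
    exon_boundaries: list[tuple[int, int]] = field(default_factory=list)
    domains: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        width = len(self.reference_row)
        for name, row in self.copies.items():
            if len(row) != width:
                raise ValidationError(
                    f"copy {name!r} row length {len(row)} != alignment width {width}"
                )
        ref = self.reference_cds
        if len(ref) % 3 == 0:
            protein = str(Seq(ref).translate())
            if "*" in protein[:-1]:
                raise ValidationError("reference CDS has an internal stop codon")

    @property
    def reference_cds(self) -> str:
        return self.reference_row.replace("-", "")

    def reference_protein(self) -> str:
        return str(Seq(self.reference_cds).translate())

    def ref_position_of_column(self) -> list[int]:
        """For each alignment column, the reference coordinate at/after it."""
        out = []
        p = 0
        for ch in self.reference_row:
            out.append(p)
            if ch != "-":
                p += 1
        return out

    @classmethod
    def from_fasta(cls, path, reference_name: str, exon_boundaries=None, domains=None):
        from Bio import SeqIO

        rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        if reference_name not in rows:
            raise ValidationError(f"reference {reference_name!r} not in {path}")
        ref_row = rows.pop(reference_name)
        return cls(
            reference_name=reference_name,
            reference_row=ref_row,
            copies=rows,
            exon_boundaries=list(exon_boundaries or []),
            domains=list(domains or []),
        )


def _exons_overlapping(aln: CdsAlignmentSet, start: int, end: int) -> tuple[int, ...]:
    hits = []
    for i, (s, e) in enumerate(aln.exon_boundaries, 1):
        if max(s, start) < min(e, end):
            hits.append(i)
    return tuple(hits)


def detect_indels(
    aln: CdsAlignmentSet, sample: str, large_deletion_min: int = 100
) -> tuple[list[LofEvent], list[LofEvent]]:
    """Classify maximal gap runs of one copy vs the reference.

    Returns ``(events, informational)``: large deletions and frameshifts
    go into *events*; in-frame indels below the size threshold go into
    *informational*.
    """
    row = aln.copies[sample]
    ref = aln.reference_row
    refpos = aln.ref_position_of_column()
    events: list[LofEvent] = []
    info: list[LofEvent] = []

    runs: list[tuple[str, int, int]] = []  # (kind, start col, end col)
    i = 0
    while i < len(row):
        if row[i] == "-" and ref[i] != "-":
            j = i
            while j < len(row) and row[j] == "-" and ref[j] != "-":
                j += 1
            runs.append(("del", i, j))
            i = j
        elif ref[i] == "-" and row[i] != "-":
            j = i
            while j < len(row) and ref[j] == "-" and row[j] != "-":
                j += 1
            runs.append(("ins", i, j))
            i = j
        else:
            i += 1

    for kind, a, b in runs:
        pos = refpos[a]
        length = (
            sum(1 for c in range(a, b) if ref[c] != "-")
            if kind == "del"
            else b - a
        )
        frameshift = length % 3 != 0
        if kind == "del" and length >= large_deletion_min:
            events.append(
                LofEvent(
                    kind="large_deletion",
                    position=pos,
                    length=length,
                    exons=_exons_overlapping(aln, pos, pos + length),
                )
            )
        if frameshift:
            events.append(LofEvent(kind="frameshift", position=pos, length=length))
        elif kind == "del" and length < large_deletion_min:
            info.append(LofEvent(kind="inframe_deletion", position=pos, length=length))
        elif kind == "ins":
            info.append(LofEvent(kind="inframe_insertion", position=pos, length=length))
    return events, info


def _haplotypes(seq: str) -> tuple[str, str]:
    """Resolve IUPAC codes into two pseudo-haplotypes (site-independent)."""
    h1 = []
    h2 = []
    for ch in seq:
        pair = AMBIG.get(ch, "NN")
        h1.append(pair[0])
        h2.append(pair[1])
    return "".join(h1), "".join(h2)


def _first_premature_stop(realized: str, ref_len: int) -> int | None:
    """Codon-start coordinate of the first stop strictly before the end.

    The final complete codon of the realized sequence corresponds to the
    reference terminator region; a stop there is not premature.
    """
    last_full = (len(realized) // 3 - 1) * 3
    for c in range(0, last_full, 3):
        codon = realized[c : c + 3]
        if codon in ("TAA", "TAG", "TGA"):
            return c
    return None


def detect_premature_stop(aln: CdsAlignmentSet, sample: str) -> list[LofEvent]:
    """First in-frame stop upstream of the reference terminator, per allele."""
    realized = aln.copies[sample].replace("-", "")
    if len(realized) < 3:
        raise ValidationError(f"{sample}: realized CDS shorter than one codon")
    ref_len = len(aln.reference_cds)
    h1, h2 = _haplotypes(realized)
    s1 = _first_premature_stop(h1, ref_len)
    s2 = _first_premature_stop(h2, ref_len)
    if s1 is None and s2 is None:
        return []
    if s1 is not None and s2 is not None:
        pos = min(s1, s2)
        zygosity = "hom"
    else:
        pos = s1 if s1 is not None else s2
        zygosity = "het" if h1 != h2 else "hom"
    return [LofEvent(kind="premature_stop", position=pos, length=3, zygosity=zygosity)]


def detect_domain_substitutions(
    aln: CdsAlignmentSet, sample: str
) -> tuple[list[LofEvent], list[LofEvent], list[str]]:
    """Nonsynonymous changes inside named domains.

    Returns ``(events, informational, skipped_domains)``.  A domain with a
    frameshift upstream of its end is flagged and not scanned, since the
    frame there is ambiguous.
    """
    row = aln.copies[sample]
    ref_row = aln.reference_row
    ref = aln.reference_cds

    # sample bases in reference coordinates (None where deleted)
    by_refpos: list[str | None] = []
    for col, ch in enumerate(ref_row):
        if ch != "-":
            by_refpos.append(row[col] if row[col] != "-" else None)

    indel_events, _ = detect_indels(aln, sample, large_deletion_min=10**9)
    fs_positions = [e.position for e in indel_events if e.kind == "frameshift"]
    skipped = [
        name
        for name, a, b in aln.domains
        if any(p < b * 3 for p in fs_positions)
    ]

    events: list[LofEvent] = []
    info: list[LofEvent] = []
    n_codons = len(ref) // 3
    for aa in range(n_codons):
        c = aa * 3
        ref_codon = ref[c : c + 3]
        bases = by_refpos[c : c + 3]
        if any(b is None or b == "N" for b in bases):
            continue
        codon = "".join(bases)
        if codon == ref_codon:
            continue
        h1, h2 = _haplotypes(codon)
        ref_aa = str(Seq(ref_codon).translate())
        aa1 = str(Seq(h1).translate())
        aa2 = str(Seq(h2).translate())
        changed = [a for a in (aa1, aa2) if a != ref_aa and a != "*"]
        if not changed:
            continue
        zygosity = "het" if aa1 != aa2 else "hom"
        domain = None
        for name, a, b in aln.domains:
            if a <= aa < b and name not in skipped:
                domain = name
                break
        ev = LofEvent(
            kind="domain_substitution" if domain else "substitution",
            position=c,
            length=3,
            zygosity=zygosity,
            domain=domain,
            aa_position=aa,
        )
        (events if domain else info).append(ev)
    return events, info, skipped


def classify(
    aln: CdsAlignmentSet, large_deletion_min: int = 100
) -> tuple[list[LofReport], dict[tuple, list[str]]]:
    """Per-sample verdicts plus shared-mutation clusters.

    Samples carrying an identical event (same kind, position, length) are
    grouped; clusters of size >= 2 indicate a shared mutation.
    """
    reports: list[LofReport] = []
    clusters: dict[tuple, list[str]] = {}
    for sample in aln.copies:
        indel_ev, indel_info = detect_indels(aln, sample, large_deletion_min)
        stop_ev = detect_premature_stop(aln, sample)
        dom_ev, dom_info, _ = detect_domain_substitutions(aln, sample)
        events = indel_ev + stop_ev + dom_ev
        reports.append(
            LofReport(sample=sample, events=events, informational=indel_info + dom_info)
        )
        for ev in events:
            clusters.setdefault(ev.identity(), []).append(sample)
    shared = {k: v for k, v in clusters.items() if len(v) >= 2}
    return reports, shared


def reports_to_rows(reports: list[LofReport]) -> list[dict]:
    """Flatten reports for a TSV (one row per event, plus intact rows)."""
    rows = []
    for rep in reports:
        if not rep.events:
            rows.append(
                {"sample": rep.sample, "verdict": rep.verdict, "kind": ".",
                 "position": ".", "length": ".", "zygosity": ".", "domain": "."}
            )
        for ev in rep.events:
            rows.append(
                {
                    "sample": rep.sample,
                    "verdict": rep.verdict,
                    "kind": ev.kind,
                    "position": ev.position,
                    "length": ev.length,
                    "zygosity": ev.zygosity,
                    "domain": ev.domain or ".",
                }
            )
    return rows
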