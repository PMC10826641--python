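"""Window construction: fixed-bp tiles and SNP-count sliding windows.

Two window systems coexist in the pipeline: nonoverlapping (or stepped)
bp windows for diversity statistics and window trees, and SNP-count
windows (e.g. 500 SNPs sliding every 125) for f_dM.  All coordinates are
0-based half-open; SNP windows also carry index ranges into the matrix's
variant-site list, with bp bounds [first SNP, last SNP + 1).
"""

from __future__ import annotations

import logging

import numpy as np

from .core import GenotypeMatrix, IntervalSet, ValidationError, Window

logger = logging.getLogger(__name__)


def bp_windows(
    scaffold_lengths: dict[str, int], size: int, step: int | None = None
) -> list[Window]:
    """Tile each scaffold with bp windows; terminal short windows flagged."""
    if size <= 0:
        raise ValidationError("window size must be > 0")
    step = size if step is None else step
    if step <= 0:
        raise ValidationError("window step must be > 0")
    out: list[Window] = []
    for scaffold, length in scaffold_lengths.items():
        start = 0
        while start < length:
            end = min(start + size, length)
            out.append(
                Window(
                    scaffold=scaffold,
                    start=start,
                    end=end,
                    partial=(end - start) < size,
                )
            )
            start += step
    return out


def snp_windows(
    matrix: GenotypeMatrix, size: int, slide: int | None = None
) -> list[Window]:
    """Windows over consecutive variant-site indices, per scaffold.

    SNPs are the matrix's segregating sites.  ``snp_start``/``snp_end``
    index the *global* variant-site array (see
    :func:`variant_site_indices`); windows never span scaffolds, and
    trailing sites that do not fill a window are not windowed.
    """
    if size <= 0:
        raise ValidationError("window size must be > 0")
    slide = size if slide is None else slide
    if slide <= 0:
        raise ValidationError("window slide must be > 0")
    var_idx = variant_site_indices(matrix)
    out: list[Window] = []
    scafs = matrix.scaffold_index[var_idx]
    for s in range(len(matrix.scaffold_names)):
        local = np.nonzero(scafs == s)[0]
        n = len(local)
        start = 0
        while start + size <= n:
            g0, g1 = local[start], local[start + size - 1]
            pos = matrix.positions[var_idx[[g0, g1]]]
            out.append(
                Window(
                    scaffold=matrix.scaffold_names[s],
                    start=int(pos[0]) - 1,
                    end=int(pos[1]),  # [first SNP, last SNP + 1)
                    snp_start=int(g0),
                    snp_end=int(g1) + 1,
                    n_snps=size,
                )
            )
            start += slide
    if not out:
        logger.warning(
            "no scaffold holds %d SNPs; SNP windowing produced no windows", size
        )
    return out


def variant_site_indices(matrix: GenotypeMatrix) -> np.ndarray:
    """Indices of segregating sites, in matrix order."""
    return np.nonzero(matrix.is_variant())[0]


def genic_fraction(window: Window, cds: IntervalSet | None) -> float:
    """Fraction of the window's bp span covered by CDS intervals."""
    if cds is None:
        return 0.0
    return cds.overlap(window.start, window.end) / window.length


def annotate_genic_fraction(
    windows: list[Window], cds_by_scaffold: dict[str, IntervalSet]
) -> list[Window]:
    for w in windows:
        w.genic_fraction = genic_fraction(w, cds_by_scaffold.get(w.scaffold))
    return windows


def alignment_window_filter(
    sequences: dict[str, str],
    max_missing_fraction: float = 0.75,
    per_individual: bool = False,
) -> tuple[bool, dict[str, str]]:
    """Missing-data filter for a window (or CDS) alignment.

    Window mode (default): drop the whole alignment iff *any* sample's N
    fraction exceeds the threshold (0.75 for 10-kb window trees).
    CDS mode (``per_individual=True``, threshold 0.5): remove offending
    individuals and keep the alignment.

    Returns ``(keep, retained_sequences)``.
    """
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) > 1:
        raise ValidationError("alignment rows have unequal lengths")
    frac = {
        name: (seq.upper().count("N") / len(seq) if seq else 1.0)
        for name, seq in sequences.items()
    }
    if per_individual:
        kept = {n: s for n, s in sequences.items() if frac[n] <= max_missing_fraction}
        return bool(kept), kept
    if any(f > max_missing_fraction for f in frac.values()):
        return False, {}
    return True, dict(sequences)


def windows_to_rows(windows: list[Window]) -> list[dict]:
    """BED-like rows for TSV output."""
    return [
        {
            "scaffold": w.scaffold,
            "start": w.start,
            "end": w.end,
            "n_snps": w.n_snps,
            "genic_fraction": (
                "NA" if w.genic_fraction is None else round(w.genic_fraction, 6)
            ),
            "flags": "partial" if w.partial else ".",
        }
        for w in windows
    ]
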