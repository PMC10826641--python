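"""Missing-data-aware windowed diversity: pi, dxy, Weir-Cockerham FST.

pi and dxy use ratio-of-sums aggregation over allele comparisons — the
window value is (total pairwise differences) / (total pairwise
comparisons), with invariant sites of an "all sites" callset contributing
comparisons to the denominator.  This estimator is unbiased under missing
data, unlike averaging per-site ratios.  Bookkeeping mirrors that logic:
``sum_missing`` counts the comparisons lost to missing genotypes, which
feeds the outlier pre-filter (drop windows with more missing counts than
actual comparisons).

FST is the two-population Weir & Cockerham (1984) estimator with observed
heterozygosity taken from genotypes; windows aggregate by the ratio of
summed variance components a / (a + b + c), never by averaging per-site
ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GenotypeMatrix, PopulationMap, ValidationError, Window


@dataclass
class DiversityRecord:
    """One window x population (or pair) diversity value with its parts."""

    window: Window
    statistic: str            # pi | dxy | fst
    populations: tuple[str, ...]
    sum_diffs: float
    sum_comparisons: float
    sum_missing: float
    value: float              # NaN when undefined

    @property
    def defined(self) -> bool:
        return np.isfinite(self.value)


def _window_counts(matrix: GenotypeMatrix, window: Window, cols: np.ndarray):
    idx = matrix.sites_in_window(window.scaffold, window.start, window.end)
    g = matrix.genotypes[np.ix_(idx, cols)]
    present = g != -1
    alt = np.where(present, g, 0).astype(np.int64).sum(axis=1)
    n = 2 * present.sum(axis=1).astype(np.int64)
    return alt, n, len(cols)


def pi_window(
    matrix: GenotypeMatrix, popmap: PopulationMap, window: Window, pop: str
) -> DiversityRecord:
    """Within-population nucleotide diversity for one window.

    Per site with n non-missing alleles of which c are alternate:
    differences = c(n-c), comparisons = n(n-1)/2.
    """
    cols = popmap.column_indices(pop, matrix.sample_ids)
    alt, n, n_samp = _window_counts(matrix, window, cols)
    diffs = alt * (n - alt)
    comps = n * (n - 1) // 2
    n_max = 2 * n_samp
    missing = n_max * (n_max - 1) // 2 - comps
    sum_c = int(comps.sum())
    return DiversityRecord(
        window=window,
        statistic="pi",
        populations=(pop,),
        sum_diffs=float(diffs.sum()),
        sum_comparisons=float(sum_c),
        sum_missing=float(missing.sum()),
        value=float(diffs.sum() / sum_c) if sum_c > 0 else float("nan"),
    )


def dxy_window(
    matrix: GenotypeMatrix, popmap: PopulationMap, window: Window, pop_a: str, pop_b: str
) -> DiversityRecord:
    """Between-population nucleotide distance for one window.

    Per site: differences = cA(nB-cB) + (nA-cA)cB over cross-population
    allele pairs, comparisons = nA * nB.
    """
    if pop_a == pop_b:
        raise ValidationError("dxy requires two distinct populations")
    cols_a = popmap.column_indices(pop_a, matrix.sample_ids)
    cols_b = popmap.column_indices(pop_b, matrix.sample_ids)
    alt_a, n_a, k_a = _window_counts(matrix, window, cols_a)
    alt_b, n_b, k_b = _window_counts(matrix, window, cols_b)
    diffs = alt_a * (n_b - alt_b) + (n_a - alt_a) * alt_b
    comps = n_a * n_b
    missing = (2 * k_a) * (2 * k_b) - comps
    sum_c = int(comps.sum())
    return DiversityRecord(
        window=window,
        statistic="dxy",
        populations=(pop_a, pop_b),
        sum_diffs=float(diffs.sum()),
        sum_comparisons=float(sum_c),
        sum_missing=float(missing.sum()),
        value=float(diffs.sum() / sum_c) if sum_c > 0 else float("nan"),
    )


def _wc_components(alt_a, n_a, het_a, alt_b, n_b, het_b):
    """Weir & Cockerham (1984) a, b, c for two populations, vectorized.

    Inputs are per-site alternate-allele counts, non-missing allele
    counts (2 x individuals) and heterozygote counts.  Sites where either
    population has < 1 genotyped individual, or the mean sample size is
    <= 1 individual, contribute nothing.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        n1 = n_a / 2.0
        n2 = n_b / 2.0
        ok = (n1 >= 1) & (n2 >= 1) & ((n1 + n2) / 2.0 > 1.0)
        n1 = np.where(ok, n1, np.nan)
        n2 = np.where(ok, n2, np.nan)
        p1 = alt_a / n_a
        p2 = alt_b / n_b
        h1 = het_a / n1
        h2 = het_b / n2
        r = 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    a = np.where(ok, a, 0.0)
    b = np.where(ok, b, 0.0)
    c = np.where(ok, c, 0.0)
    return np.nan_to_num(a), np.nan_to_num(b), np.nan_to_num(c)


def fst_window(
    matrix: GenotypeMatrix, popmap: PopulationMap, window: Window, pop_a: str, pop_b: str
) -> DiversityRecord:
    """Weir-Cockerham FST aggregated as sum(a) / sum(a + b + c)."""
    if pop_a == pop_b:
        raise ValidationError("FST requires two distinct populations")
    cols_a = popmap.column_indices(pop_a, matrix.sample_ids)
    cols_b = popmap.column_indices(pop_b, matrix.sample_ids)
    idx = matrix.sites_in_window(window.scaffold, window.start, window.end)

    def counts(cols):
        g = matrix.genotypes[np.ix_(idx, cols)]
        present = g != -1
        alt = np.where(present, g, 0).astype(np.int64).sum(axis=1)
        n = 2 * present.sum(axis=1).astype(np.int64)
        het = (g == 1).sum(axis=1).astype(np.int64)
        return alt, n, het

    alt_a, n_a, het_a = counts(cols_a)
    alt_b, n_b, het_b = counts(cols_b)
    a, b, c = _wc_components(alt_a, n_a, het_a, alt_b, n_b, het_b)
    num = float(a.sum())
    den = float((a + b + c).sum())
    return DiversityRecord(
        window=window,
        statistic="fst",
        populations=(pop_a, pop_b),
        sum_diffs=num,
        sum_comparisons=den,
        sum_missing=0.0,
        value=num / den if den != 0.0 else float("nan"),
    )


def dxy_outliers(
    records: list[DiversityRecord], z_threshold: float = 3.0
) -> set[tuple[str, int, int]]:
    """Windows whose dxy exceeds the genome-wide mean by z_threshold SDs.

    Windows with more missing counts than comparisons are removed before
    the mean/SD are taken (sample SD, n-1 denominator); an SD of zero
    yields no outliers.
    """
    retained = [
        r
        for r in records
        if r.defined and not r.sum_missing > r.sum_comparisons
    ]
    if len(retained) < 2:
        raise ValidationError("need >= 2 retained windows for outlier detection")
    values = np.array([r.value for r in retained])
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0:
        return set()
    z = (values - mean) / sd
    return {r.window.key() for r, zi in zip(retained, z) if zi > z_threshold}


def shared_outliers(
    set_a: set[tuple[str, int, int]], set_b: set[tuple[str, int, int]]
) -> set[tuple[str, int, int]]:
    """Exact intersection of two outlier window sets."""
    return set_a & set_b


def diversity_table(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    windows: list[Window],
    pops: list[str] | None = None,
):
    """Pandas table of pi per population and dxy/FST per pair per window."""
    import itertools

    import pandas as pd

    pops = pops or popmap.populations
    rows = []
    for w in windows:
        for pop in pops:
            rec = pi_window(matrix, popmap, w, pop)
            rows.append(_record_row(rec))
        for pa, pb in itertools.combinations(pops, 2):
            rows.append(_record_row(dxy_window(matrix, popmap, w, pa, pb)))
            rows.append(_record_row(fst_window(matrix, popmap, w, pa, pb)))
    return pd.DataFrame(rows)


def _record_row(rec: DiversityRecord) -> dict:
    return {
        "statistic": rec.statistic,
        "populations": "/".join(rec.populations),
        "scaffold": rec.window.scaffold,
        "start": rec.window.start,
        "end": rec.window.end,
        "sum_diffs": rec.sum_diffs,
        "sum_comparisons": rec.sum_comparisons,
        "sum_missing": rec.sum_missing,
        "value": rec.value,
    }
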