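"""Four-taxon site-pattern statistics: D, f4-ratio, f_dM and f-branch.

All statistics run on population alternate-allele frequencies (p1, p2,
p3, p4) for an oriented trio (P1, P2, P3) plus outgroup.  Per site,

    ABBA = (1 - p1) p2 p3 (1 - p4)
    BABA = p1 (1 - p2) p3 (1 - p4)

D = (sum ABBA - sum BABA) / (sum ABBA + sum BABA); gene flow between P3
and P2 pushes D positive, P3 and P1 negative, while incomplete lineage
sorting alone leaves its expectation at zero.  Significance comes from a
delete-one block jackknife over contiguous equal-SNP blocks.

The f4-ratio estimates the admixture fraction f contributed by the donor;
f_dM is its windowed, symmetrised relative for scanning chromosomes; the
f-branch metric assigns correlated f4-ratio signals to specific branches
of a guide tree.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats

from .core import GenotypeMatrix, PopulationMap, ValidationError, Window

logger = logging.getLogger(__name__)


@dataclass
class SitePatternSums:
    sum_abba: float = 0.0
    sum_baba: float = 0.0
    sum_denominator_fdm: float = 0.0
    n_sites_used: int = 0


@dataclass
class TrioResult:
    p1: str
    p2: str
    p3: str
    outgroup: str
    d: float
    z: float
    p_value: float
    f4_ratio: float
    n_sites_used: int
    degenerate: bool = False
    significant: bool = False


# ---------------------------------------------------------------------------
# Frequencies and per-site pattern terms


def population_frequencies(
    matrix: GenotypeMatrix, popmap: PopulationMap, pops: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Alternate-allele frequency and allele count per site per population.

    Returns ``(p, n)`` of shape ``(n_sites, len(pops))``; ``p`` is NaN
    where a population has no non-missing allele.
    """
    seen = [popmap.column_indices(pop, matrix.sample_ids) for pop in pops]
    flat = np.concatenate(seen)
    if len(np.unique(flat)) != len(flat):
        raise ValidationError("overlapping population memberships in trio")
    p = np.empty((matrix.n_sites, len(pops)))
    n = np.empty((matrix.n_sites, len(pops)), dtype=np.int64)
    for k, cols in enumerate(seen):
        alt, tot = matrix.allele_counts(cols)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[:, k] = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
        n[:, k] = tot
    return p, n


def _pattern_terms(p: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(abba, baba, used-mask) per site for a 4-column frequency array."""
    used = ~np.isnan(p).any(axis=1)
    q = np.where(used[:, None], p, 0.0)
    p1, p2, p3, p4 = q.T
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    return np.where(used, abba, 0.0), np.where(used, baba, 0.0), used


def _fdm_denominator_terms(p: np.ndarray, used: np.ndarray) -> np.ndarray:
    """Per-site f_dM denominator, conditioned on the sign of (p2 - p1).

    When P2 looks like the recipient (p2 > p1) the donor-frequency proxy
    pD = max(p2, p3) replaces both p2 and p3; otherwise pD = max(p1, p3)
    replaces both p1 and p3 and the term is negated.  This choice makes
    f_dM exactly antisymmetric under a P1/P2 swap and bounds |f_dM| by 1.
    """
    q = np.where(used[:, None], p, 0.0)
    p1, p2, p3, p4 = q.T
    pd2 = np.maximum(p2, p3)
    den2 = (1 - p1) * pd2 * pd2 * (1 - p4) - p1 * (1 - pd2) * pd2 * (1 - p4)
    pd1 = np.maximum(p1, p3)
    den1 = -((1 - pd1) * p2 * pd1 * (1 - p4) - pd1 * (1 - p2) * pd1 * (1 - p4))
    den = np.where(p2 >= p1, den2, den1)
    return np.where(used, den, 0.0)


def site_patterns(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    pops: tuple[str, str, str, str],
    sites: np.ndarray | slice | None = None,
) -> SitePatternSums:
    """Accumulate ABBA/BABA (and f_dM denominator) sums over sites."""
    p, _ = population_frequencies(matrix, popmap, pops)
    if sites is not None:
        p = p[sites]
    abba, baba, used = _pattern_terms(p)
    den = _fdm_denominator_terms(p, used)
    return SitePatternSums(
        sum_abba=float(abba.sum()),
        sum_baba=float(baba.sum()),
        sum_denominator_fdm=float(den.sum()),
        n_sites_used=int(used.sum()),
    )


def d_statistic(patterns: SitePatternSums) -> float:
    """D = (ABBA - BABA) / (ABBA + BABA); NaN when no informative sites."""
    total = patterns.sum_abba + patterns.sum_baba
    if total == 0:
        logger.warning("no informative sites: D undefined")
        return float("nan")
    return (patterns.sum_abba - patterns.sum_baba) / total


# ---------------------------------------------------------------------------
# Jackknife


def _informative_mask(p: np.ndarray) -> np.ndarray:
    """Sites usable for a trio: all four populations genotyped, and the
    site segregating among them."""
    used = ~np.isnan(p).any(axis=1)
    q = np.where(used[:, None], p, 0.0)
    poly = (q.max(axis=1) - q.min(axis=1)) > 0
    return used & poly


def jackknife(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    pops: tuple[str, str, str, str],
    n_blocks: int = 20,
) -> tuple[float, float, float, bool]:
    """Genome-wide D with delete-one block-jackknife Z and p.

    Blocks are contiguous, equal-SNP partitions of the informative sites
    (matrix order, hence respecting scaffold order).  Returns
    ``(D, Z, p, degenerate)``; the degenerate flag marks SE = 0.
    """
    if n_blocks < 2:
        raise ValidationError("need >= 2 jackknife blocks")
    p, _ = population_frequencies(matrix, popmap, pops)
    info = np.nonzero(_informative_mask(p))[0]
    if len(info) < n_blocks:
        raise ValidationError(
            f"{len(info)} informative sites < {n_blocks} jackknife blocks"
        )
    abba, baba, _ = _pattern_terms(p[info])
    A, B = abba.sum(), baba.sum()
    d_full = (A - B) / (A + B) if (A + B) > 0 else float("nan")

    bounds = np.linspace(0, len(info), n_blocks + 1).astype(int)
    d_loo = np.empty(n_blocks)
    for j in range(n_blocks):
        a_j = abba[bounds[j] : bounds[j + 1]].sum()
        b_j = baba[bounds[j] : bounds[j + 1]].sum()
        denom = (A - a_j) + (B - b_j)
        d_loo[j] = ((A - a_j) - (B - b_j)) / denom if denom > 0 else 0.0
    se = np.sqrt((n_blocks - 1) / n_blocks * ((d_loo - d_loo.mean()) ** 2).sum())
    if se == 0:
        return d_full, float("nan"), float("nan"), True
    z = d_full / se
    p_value = 2.0 * sp_stats.norm.sf(abs(z))
    return d_full, float(z), float(p_value), False


# ---------------------------------------------------------------------------
# f4-ratio


def _f4_sums(p: np.ndarray) -> tuple[float, float]:
    """(numerator, denominator) site sums of the f4-ratio for one trio."""
    used = ~np.isnan(p).any(axis=1)
    q = np.where(used[:, None], p, 0.0)
    p1, p2, p3, p4 = q.T
    num = p3 * (1 - p4) * (p2 - p1)
    den = p3 * (1 - p4) * (p3 - p1)
    return float(num[used].sum()), float(den[used].sum())


def f4_ratio(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    pops: tuple[str, str, str, str],
    sites: np.ndarray | slice | None = None,
) -> float:
    """Admixture-fraction estimate f = S(P1,P2;P3,O) / S(P1,P3;P3,O)."""
    p, _ = population_frequencies(matrix, popmap, pops)
    if sites is not None:
        p = p[sites]
    num, den = _f4_sums(p)
    if den == 0:
        logger.warning("f4-ratio denominator is zero")
        return float("nan")
    return num / den


# ---------------------------------------------------------------------------
# Windowed f_dM


def fdm_windows(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    pops: tuple[str, str, str, str],
    windows: list[Window],
):
    """Per-window f_dM over SNP-count windows (pandas DataFrame).

    Positive values indicate P2-P3 allele sharing, negative P1-P3;
    windows with a zero denominator get NaN.
    """
    import pandas as pd

    from .windows import variant_site_indices

    p, _ = population_frequencies(matrix, popmap, pops)
    var_idx = variant_site_indices(matrix)
    pv = p[var_idx]
    abba, baba, used = _pattern_terms(pv)
    num = abba - baba
    den = _fdm_denominator_terms(pv, used)
    cnum = np.concatenate([[0.0], np.cumsum(num)])
    cden = np.concatenate([[0.0], np.cumsum(den)])
    rows = []
    for w in windows:
        if w.snp_start is None or w.snp_end is None:
            raise ValidationError("f_dM needs SNP-count windows")
        wn = cnum[w.snp_end] - cnum[w.snp_start]
        wd = cden[w.snp_end] - cden[w.snp_start]
        rows.append(
            {
                "scaffold": w.scaffold,
                "start": w.start,
                "end": w.end,
                "n_snps": w.n_snps,
                "genic_fraction": w.genic_fraction,
                "fdm": wn / wd if wd != 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def fdm_single_window(p: np.ndarray) -> float:
    """f_dM of one window given its per-site frequency array (testing aid)."""
    abba, baba, used = _pattern_terms(p)
    den = _fdm_denominator_terms(p, used)
    total = den.sum()
    return float((abba - baba).sum() / total) if total != 0 else float("nan")


# ---------------------------------------------------------------------------
# Trio enumeration on a guide tree


def _leaf_sets(tree) -> list[frozenset]:
    return [
        frozenset(l.taxon.label for l in node.leaf_iter())
        for node in tree.preorder_node_iter()
    ]


def enumerate_trios(
    guide_tree, outgroup: str, populations: list[str] | None = None
) -> list[tuple[str, str, str, bool]]:
    """All population triples oriented so (P1, P2) are the guide-tree cherry.

    Returns ``(P1, P2, P3, tie_broken)`` tuples; P1 < P2 lexicographically,
    and under a polytomy the orientation falls back to lexicographic order
    with the flag set.
    """
    tips = {l.taxon.label for l in guide_tree.leaf_node_iter()}
    if populations is None:
        populations = sorted(tips - {outgroup})
    missing = set(populations) - tips
    if missing:
        raise ValidationError(f"populations absent from guide tree: {sorted(missing)}")
    clades = _leaf_sets(guide_tree)
    out = []
    for triple in itertools.combinations(sorted(populations), 3):
        best_pair = None
        for pair in itertools.combinations(triple, 2):
            other = next(t for t in triple if t not in pair)
            # smallest clade containing the pair
            containing = [c for c in clades if set(pair) <= c]
            mrca = min(containing, key=len)
            if other not in mrca:
                best_pair = tuple(sorted(pair))
                break
        if best_pair is None:
            a, b, c = sorted(triple)
            out.append((a, b, c, True))
        else:
            p3 = next(t for t in triple if t not in best_pair)
            out.append((best_pair[0], best_pair[1], p3, False))
    return out


def all_trio_tests(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    guide_tree,
    outgroup: str,
    n_blocks: int = 20,
    alpha: float = 0.05,
) -> list[TrioResult]:
    """D + jackknife + f4-ratio for every trio, Bonferroni-corrected."""
    trios = enumerate_trios(guide_tree, outgroup)
    results = []
    for p1, p2, p3, _tie in trios:
        pops = (p1, p2, p3, outgroup)
        d, z, p_value, degenerate = jackknife(matrix, popmap, pops, n_blocks)
        f = f4_ratio(matrix, popmap, pops)
        patterns = site_patterns(matrix, popmap, pops)
        results.append(
            TrioResult(
                p1=p1, p2=p2, p3=p3, outgroup=outgroup,
                d=d, z=z, p_value=p_value, f4_ratio=f,
                n_sites_used=patterns.n_sites_used, degenerate=degenerate,
            )
        )
    threshold = alpha / max(len(results), 1)
    for r in results:
        r.significant = (not r.degenerate) and np.isfinite(r.p_value) and (
            r.p_value < threshold
        )
    return results


# ---------------------------------------------------------------------------
# f-branch


@dataclass
class FBranchMatrix:
    """f_b values per (guide-tree branch, tip); NaN marks INVALID cells."""

    branches: list[frozenset]          # descendant tip sets of each branch b
    tips: list[str]
    values: np.ndarray                 # (n_branches, n_tips), NaN = invalid
    z_scores: np.ndarray
    significant: np.ndarray            # bool

    def to_dataframe(self):
        import pandas as pd

        index = [",".join(sorted(b)) for b in self.branches]
        return pd.DataFrame(self.values, index=index, columns=self.tips)


def f_branch(
    guide_tree,
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    outgroup: str,
    n_blocks: int = 20,
    z_threshold: float = 3.0,
) -> FBranchMatrix:
    """Assign excess allele sharing to guide-tree branches.

    For branch b with sister s and candidate tip C (descending from
    neither), f_b(C) = median over B in tips(s) of [min over A in tips(b)
    of f4_ratio(B, A, C, O)], negatives truncated at 0.  Cells where C
    descends from b or s are INVALID (NaN) — such tests are inconsistent
    with the guide-tree topology.  Significance is a block jackknife of
    the whole median-min statistic (Z > ``z_threshold``).
    """
    tips_all = sorted(
        l.taxon.label for l in guide_tree.leaf_node_iter() if l.taxon.label != outgroup
    )
    # (branch tip set, sister tip set) for every non-root branch with a
    # resolved sister, excluding the outgroup side
    pairs: list[tuple[frozenset, frozenset]] = []
    for node in guide_tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        siblings = [c for c in node.parent_node.child_nodes() if c is not node]
        if len(siblings) != 1:
            logger.warning("unresolved guide tree at a branch; skipped")
            continue
        own = frozenset(l.taxon.label for l in node.leaf_iter())
        sis = frozenset(l.taxon.label for l in siblings[0].leaf_iter())
        if outgroup in own or outgroup in sis:
            continue
        if own | sis == set(tips_all):
            continue  # no external candidate C exists
        pairs.append((own, sis))

    # Pre-compute per-block f4 sums for every needed trio.
    p_all, _ = population_frequencies(
        matrix, popmap, tuple(tips_all) + (outgroup,)
    )
    col = {pop: k for k, pop in enumerate(tips_all)}
    col[outgroup] = len(tips_all)
    n_sites = p_all.shape[0]
    bounds = np.linspace(0, n_sites, n_blocks + 1).astype(int)

    def block_sums(trio: tuple[str, str, str]) -> tuple[np.ndarray, np.ndarray]:
        idx = [col[trio[0]], col[trio[1]], col[trio[2]], col[outgroup]]
        p = p_all[:, idx]
        used = ~np.isnan(p).any(axis=1)
        q = np.where(used[:, None], p, 0.0)
        num = q[:, 2] * (1 - q[:, 3]) * (q[:, 1] - q[:, 0])
        den = q[:, 2] * (1 - q[:, 3]) * (q[:, 2] - q[:, 0])
        nb = np.array([num[bounds[j] : bounds[j + 1]].sum() for j in range(n_blocks)])
        db = np.array([den[bounds[j] : bounds[j + 1]].sum() for j in range(n_blocks)])
        return nb, db

    cache: dict[tuple[str, str, str], tuple[np.ndarray, np.ndarray]] = {}

    def f4_from(nb, db, drop: int | None) -> float:
        if drop is None:
            n, d = nb.sum(), db.sum()
        else:
            n = nb.sum() - nb[drop]
            d = db.sum() - db[drop]
        return n / d if d != 0 else np.nan

    def fb_value(own: frozenset, sis: frozenset, c: str, drop: int | None) -> float:
        meds = []
        for b_tip in sorted(sis):
            mins = []
            for a_tip in sorted(own):
                trio = (b_tip, a_tip, c)
                if trio not in cache:
                    cache[trio] = block_sums(trio)
                nb, db = cache[trio]
                mins.append(f4_from(nb, db, drop))
            meds.append(np.nanmin(mins) if mins else np.nan)
        return float(np.nanmedian(meds))

    values = np.full((len(pairs), len(tips_all)), np.nan)
    zs = np.full((len(pairs), len(tips_all)), np.nan)
    sig = np.zeros((len(pairs), len(tips_all)), dtype=bool)
    for i, (own, sis) in enumerate(pairs):
        for j, c in enumerate(tips_all):
            if c in own or c in sis:
                continue  # INVALID cell
            fb = fb_value(own, sis, c, drop=None)
            loo = np.array([fb_value(own, sis, c, drop=k) for k in range(n_blocks)])
            se = np.sqrt((n_blocks - 1) / n_blocks * ((loo - loo.mean()) ** 2).sum())
            z = fb / se if se > 0 else np.nan
            values[i, j] = max(fb, 0.0)
            zs[i, j] = z
            sig[i, j] = bool(np.isfinite(z) and z > z_threshold and fb > 0)
    return FBranchMatrix(
        branches=[own for own, _ in pairs],
        tips=tips_all,
        values=values,
        z_scores=zs,
        significant=sig,
    )


# ---------------------------------------------------------------------------
# Candidate-region elevation test


def region_elevation_test(
    fdm_table, scaffold: str, region: tuple[int, int]
) -> tuple[float, float, float]:
    """One-tailed test of region f_dM against the scaffold-wide mean.

    ``fdm_table`` is the DataFrame from :func:`fdm_windows`.  Returns
    ``(mean difference, t, upper-tailed p)``; p = 0.5 when the region sits
    exactly at the scaffold mean.
    """
    sub = fdm_table[(fdm_table["scaffold"] == scaffold) & fdm_table["fdm"].notna()]
    if len(sub) < 2:
        raise ValidationError("need >= 2 windows on the scaffold")
    start, end = region
    in_region = sub[(sub["end"] > start) & (sub["start"] < end)]
    if len(in_region) < 2:
        raise ValidationError("need >= 2 windows overlapping the region")
    scaffold_mean = float(sub["fdm"].mean())
    values = in_region["fdm"].to_numpy()
    diff = float(values.mean() - scaffold_mean)
    if values.std(ddof=1) < 1e-12 * max(1.0, float(np.abs(values).max())):
        # constant region: the t statistic is 0 or +/- infinity by sign
        flat = abs(diff) < 1e-12 * max(1.0, abs(scaffold_mean))
        t = 0.0 if flat else float(np.sign(diff) * np.inf)
        p = 0.5 if flat else (0.0 if diff > 0 else 1.0)
        return diff, t, p
    res = sp_stats.ttest_1samp(values, popmean=scaffold_mean, alternative="greater")
    return diff, float(res.statistic), float(res.pvalue)
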