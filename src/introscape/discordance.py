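"""Tree-discordance landscape: normalized RF, topology weights, gCF/sCF.

Topology weighting follows the TWISST idea: with several samples per
taxon, each one-tip-per-taxon subsample of a window tree induces a
taxon-level topology, and a topology's weight is the fraction of
subsamples inducing it.  Enumeration is exact up to a combination budget,
then falls back to seeded uniform sampling with a Monte-Carlo standard
error.  Unrooted topologies are identified by their canonical set of
nontrivial bipartitions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .core import ValidationError

logger = logging.getLogger(__name__)

TopologyKey = frozenset  # frozenset of canonical splits (frozensets of taxa)


# ---------------------------------------------------------------------------
# Bipartition utilities


def _clades(tree) -> list[frozenset]:
    """Leaf-label sets below every internal non-root node."""
    out = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        out.append(frozenset(l.taxon.label for l in node.leaf_iter()))
    return out


def _canonical_split(side: frozenset, labels: frozenset) -> frozenset:
    """Represent a split by the side *not* containing the smallest label."""
    anchor = min(labels)
    return labels - side if anchor in side else side


def restricted_splits(tree, labels: set | None = None) -> set[frozenset]:
    """Nontrivial splits of the tree, restricted to a label subset."""
    tip_labels = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    labels = frozenset(labels) if labels is not None else tip_labels
    out: set[frozenset] = set()
    for clade in _clades(tree):
        side = frozenset(clade & labels)
        if 2 <= len(side) <= len(labels) - 2:
            out.add(_canonical_split(side, labels))
    return out


def rf_normalized(tree1, tree2) -> float:
    """Normalized Robinson-Foulds distance in [0, 1].

    Trees are compared on their shared tips (with a warning when pruning
    was needed); the symmetric-difference count of nontrivial splits is
    divided by the total number of internal splits in the two trees —
    2(n-3) for binary trees of n tips.
    """
    l1 = {l.taxon.label for l in tree1.leaf_node_iter()}
    l2 = {l.taxon.label for l in tree2.leaf_node_iter()}
    shared = l1 & l2
    if len(shared) < 4:
        raise ValidationError(f"need >= 4 shared tips, got {len(shared)}")
    if shared != l1 or shared != l2:
        logger.warning("trees pruned to %d shared tips for RF", len(shared))
    s1 = restricted_splits(tree1, shared)
    s2 = restricted_splits(tree2, shared)
    denom = len(s1) + len(s2)
    if denom == 0:
        return 0.0
    return len(s1 ^ s2) / denom


# ---------------------------------------------------------------------------
# Topology weighting


@dataclass
class TopologyWeighting:
    weights: dict[TopologyKey, float]
    taxa: tuple[str, ...]
    method: str                       # exact | sampled
    n_combinations_evaluated: int
    mc_se: dict[TopologyKey, float] | None = None

    def weight_sum(self) -> float:
        return sum(self.weights.values())


def _induced_key(
    clades: list[frozenset], combo: dict[str, str], taxa: frozenset
) -> TopologyKey:
    """Taxon-level topology induced by one tip choice per taxon."""
    tip_to_taxon = {tip: taxon for taxon, tip in combo.items()}
    chosen = set(tip_to_taxon)
    splits = set()
    k = len(taxa)
    for clade in clades:
        side = frozenset(tip_to_taxon[t] for t in clade & chosen)
        if 2 <= len(side) <= k - 2:
            splits.add(_canonical_split(side, taxa))
    return frozenset(splits)


def topology_weights(
    window_tree,
    taxon_map: dict[str, str],
    taxa: list[str],
    max_exact: int = 10_000,
    seed: int | None = None,
    n_samples: int = 2_000,
) -> TopologyWeighting:
    """TWISST-style weights of taxon-level topologies for one window tree.

    ``taxon_map`` maps tree tip labels to taxa; tips mapping outside
    ``taxa`` are ignored.  Exact enumeration is used when the number of
    one-tip-per-taxon combinations is at most ``max_exact``, otherwise
    ``n_samples`` seeded uniform draws with a reported Monte-Carlo SE.
    """
    taxa_set = frozenset(taxa)
    tips_by_taxon: dict[str, list[str]] = {t: [] for t in taxa}
    for leaf in window_tree.leaf_node_iter():
        taxon = taxon_map.get(leaf.taxon.label)
        if taxon in tips_by_taxon:
            tips_by_taxon[taxon].append(leaf.taxon.label)
    for t, tips in tips_by_taxon.items():
        if not tips:
            raise ValidationError(f"taxon {t!r} has no tips in the window tree")
    clades = _clades(window_tree)

    total = 1
    for tips in tips_by_taxon.values():
        total *= len(tips)
    counts: dict[TopologyKey, int] = {}
    if total <= max_exact:
        for choice in itertools.product(*(tips_by_taxon[t] for t in taxa)):
            key = _induced_key(clades, dict(zip(taxa, choice)), taxa_set)
            counts[key] = counts.get(key, 0) + 1
        n_eval = total
        weights = {k: v / total for k, v in counts.items()}
        return TopologyWeighting(weights, tuple(taxa), "exact", n_eval)
    rng = np.random.default_rng(seed)
    for _ in range(n_samples):
        choice = {
            t: tips_by_taxon[t][int(rng.integers(len(tips_by_taxon[t])))] for t in taxa
        }
        key = _induced_key(clades, choice, taxa_set)
        counts[key] = counts.get(key, 0) + 1
    weights = {k: v / n_samples for k, v in counts.items()}
    mc_se = {
        k: float(np.sqrt(w * (1 - w) / n_samples)) for k, w in weights.items()
    }
    return TopologyWeighting(weights, tuple(taxa), "sampled", n_samples, mc_se)


def topology_newick(key: TopologyKey, taxa: tuple[str, ...]) -> str:
    """Canonical newick rendering of an unrooted topology key.

    The tree is displayed rooted at the smallest taxon label; split sides
    (which never contain that label) form a laminar set of clades.
    """
    taxa_set = frozenset(taxa)
    anchor = min(taxa_set)
    others = sorted(taxa_set - {anchor})
    clades = sorted(key, key=len, reverse=True)

    def render(members: list[str], available: list[frozenset]) -> str:
        parts = []
        used: set[str] = set()
        for i, clade in enumerate(available):
            if set(clade) <= set(members) and not (set(clade) & used):
                inner = render(sorted(clade), [c for c in available[i + 1 :] if c < clade])
                parts.append(inner)
                used |= set(clade)
        for m in members:
            if m not in used:
                parts.append(m)
        return "(" + ",".join(sorted(parts)) + ")"

    return f"({anchor},{render(others, clades)[1:-1]});"


def internal_branch_weight(
    weighting: TopologyWeighting,
    branch_def: set[str],
    guide_tree=None,
) -> float:
    """Summed weight of topologies where ``branch_def`` forms a clade.

    ``branch_def`` should be a clade of the guide tree (warned otherwise,
    still computed).  A clade "relative to the outgroup" of an unrooted
    k-taxon topology is the split branch_def | everything-else.
    """
    taxa = frozenset(weighting.taxa)
    branch = frozenset(branch_def)
    if not branch < taxa:
        raise ValidationError("branch_def must be a proper subset of the taxa")
    if guide_tree is not None:
        guide_clades = {frozenset(c) for c in _clades(guide_tree)}
        if branch not in guide_clades:
            logger.warning("branch_def %s is not a guide-tree clade", sorted(branch))
    if len(branch) < 2 or len(branch) > len(taxa) - 2:
        return float(sum(weighting.weights.values()))  # trivially a clade
    target = _canonical_split(branch, taxa)
    return float(
        sum(w for key, w in weighting.weights.items() if target in key)
    )


# ---------------------------------------------------------------------------
# Concordance factors


@dataclass
class ConcordanceRecord:
    branch: frozenset                 # one side of the species-tree split
    gcf: float | None = None
    gcf_n_decisive: int = 0
    scf: float | None = None
    scf_n_quartets: int = 0


def _branch_blocks(species_tree):
    """Per internal branch: (split side, four surrounding tip blocks).

    Requires the relevant nodes to be binary; raises otherwise.
    """
    all_leaves = frozenset(l.taxon.label for l in species_tree.leaf_node_iter())
    seen: set[frozenset] = set()
    out = []
    for node in species_tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        canon = _canonical_split(side, all_leaves)
        if canon in seen:
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise ValidationError("concordance factors require a binary species tree")
        a1 = frozenset(l.taxon.label for l in children[0].leaf_iter())
        a2 = frozenset(l.taxon.label for l in children[1].leaf_iter())
        parent = node.parent_node
        siblings = [c for c in parent.child_nodes() if c is not node]
        if parent.parent_node is None:
            if len(siblings) == 1:
                sib = siblings[0]
                sib_children = sib.child_nodes()
                if len(sib_children) != 2:
                    raise ValidationError(
                        "concordance factors require a binary species tree"
                    )
                b1 = frozenset(l.taxon.label for l in sib_children[0].leaf_iter())
                b2 = frozenset(l.taxon.label for l in sib_children[1].leaf_iter())
            elif len(siblings) == 2:  # unrooted trifurcation at the root
                b1 = frozenset(l.taxon.label for l in siblings[0].leaf_iter())
                b2 = frozenset(l.taxon.label for l in siblings[1].leaf_iter())
            else:
                raise ValidationError(
                    "concordance factors require a binary species tree"
                )
        else:
            if len(siblings) != 1:
                raise ValidationError(
                    "concordance factors require a binary species tree"
                )
            b1 = frozenset(l.taxon.label for l in siblings[0].leaf_iter())
            b2 = all_leaves - side - b1
            if not b2:
                continue
        seen.add(canon)
        out.append((side, (a1, a2, b1, b2)))
    if not out:
        raise ValidationError("species tree has no internal branches")
    return out


def gene_concordance(gene_trees, species_tree) -> list[ConcordanceRecord]:
    """Gene concordance factor per internal species-tree branch.

    A gene tree is decisive for a branch iff it holds at least one tip in
    each of the four subtrees around the branch; gCF is the percentage of
    decisive trees whose induced split matches the branch.
    """
    records = []
    gene_info = []
    for gt in gene_trees:
        leaves = frozenset(l.taxon.label for l in gt.leaf_node_iter())
        gene_info.append((leaves, _clades(gt)))
    for side, blocks in _branch_blocks(species_tree):
        decisive = 0
        concordant = 0
        for leaves, clades in gene_info:
            if any(not (block & leaves) for block in blocks):
                continue
            decisive += 1
            target = side & leaves
            for clade in clades:
                cl = clade & leaves
                if cl == target or leaves - cl == target:
                    concordant += 1
                    break
        records.append(
            ConcordanceRecord(
                branch=side,
                gcf=(100.0 * concordant / decisive) if decisive else None,
                gcf_n_decisive=decisive,
            )
        )
    return records


def site_concordance(
    alignment: dict[str, str],
    species_tree,
    n_quartets: int = 100,
    seed: int | None = None,
    taxon_map: dict[str, str] | None = None,
) -> list[ConcordanceRecord]:
    """Site concordance factor per branch, from sampled quartets.

    For each branch, ``n_quartets`` quartets are drawn (one sequence from
    each of the four surrounding blocks); a site is decisive for a quartet
    when it shows exactly two states, each carried by two members, and it
    supports the concordant pairing when the two same-side members share a
    state.  sCF is the mean over quartets of the concordant percentage;
    quartets without decisive sites are skipped.
    """
    if n_quartets < 1:
        raise ValidationError("n_quartets must be >= 1")
    rng = np.random.default_rng(seed)
    names = list(alignment)
    by_taxon: dict[str, list[str]] = {}
    for name in names:
        taxon = taxon_map.get(name) if taxon_map else name
        if taxon is not None:
            by_taxon.setdefault(taxon, []).append(name)
    arr = {n: np.frombuffer(alignment[n].upper().encode(), dtype="S1") for n in names}
    valid = {b"A", b"C", b"G", b"T"}

    records = []
    for side, blocks in _branch_blocks(species_tree):
        members = []
        for block in blocks:
            avail = [n for t in block for n in by_taxon.get(t, [])]
            members.append(avail)
        if any(not m for m in members):
            records.append(ConcordanceRecord(branch=side, scf=None))
            continue
        vals = []
        for _ in range(n_quartets):
            quartet = [m[int(rng.integers(len(m)))] for m in members]
            s = np.vstack([arr[q] for q in quartet])
            ok = np.ones(s.shape[1], dtype=bool)
            for b in range(4):
                ok &= np.isin(s[b], list(valid))
            cols = s[:, ok]
            same12 = cols[0] == cols[1]
            same34 = cols[2] == cols[3]
            same13 = cols[0] == cols[2]
            same14 = cols[0] == cols[3]
            same23 = cols[1] == cols[2]
            same24 = cols[1] == cols[3]
            conc = same12 & same34 & ~same13
            disc1 = same13 & same24 & ~same12
            disc2 = same14 & same23 & ~same12
            decisive = int(conc.sum() + disc1.sum() + disc2.sum())
            if decisive:
                vals.append(100.0 * int(conc.sum()) / decisive)
        records.append(
            ConcordanceRecord(
                branch=side,
                scf=float(np.mean(vals)) if vals else None,
                scf_n_quartets=len(vals),
            )
        )
    return records
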