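"""Synthetic-data generator: MSC gene trees, SNPs, scaffolds, LOF fixtures.

Gene trees are drawn under the multispecies coalescent on a species tree
with branch lengths in coalescent units (2N generations): within a
species-tree branch, each pair of lineages coalesces at rate 1.
Introgression is modelled as an instantaneous pulse — at the event time,
every lineage currently in the recipient branch jumps to the donor branch
independently with probability f — so the admixture fraction f is exactly
the quantity the f4-ratio estimates.

Mutations follow an infinite-sites model: each SNP falls on one gene-tree
branch (chosen proportionally to branch length) and the derived allele is
carried by exactly the tips below that branch.  Haploid tips are paired
into diploid samples.  Each gene tree owns a fixed-width coordinate block
on a scaffold, so genomic windows cut across trees the way recombination
makes them cut across genealogies in real data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .core import GenotypeMatrix, IntervalSet, PopulationMap, ValidationError
from .lof import CdsAlignmentSet

STOP_CODONS = ("TAA", "TAG", "TGA")
_IUPAC_PAIR = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


@dataclass
class MigrationPulse:
    """Instantaneous migration: recipient lineages jump to the donor branch.

    ``donor`` and ``recipient`` name a taxon (str) or a clade (iterable of
    taxon labels); the branch is the one above that clade's MRCA.  ``time``
    is in coalescent units before the present and must lie inside both
    branches' existence intervals.
    """

    donor: str | tuple[str, ...]
    recipient: str | tuple[str, ...]
    time: float
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValidationError("migrant fraction must be in [0, 1]")
        if self._key(self.donor) == self._key(self.recipient):
            raise ValidationError("donor and recipient must differ")

    @staticmethod
    def _key(spec) -> frozenset:
        return frozenset([spec]) if isinstance(spec, str) else frozenset(spec)


@dataclass
class SpeciesTreeModel:
    """Species tree + sampling design + migration scenario.

    ``newick`` has branch lengths in coalescent units; tips are taxa.
    ``samples_per_taxon`` gives diploid sample counts (``ploidy=1`` turns
    samples into haploid lineages, useful for textbook topology checks).
    """

    newick: str
    samples_per_taxon: dict[str, int]
    migration: list[MigrationPulse] = field(default_factory=list)
    ploidy: int = 2

    def __post_init__(self) -> None:
        self._tree = dendropy.Tree.get(
            data=self.newick, schema="newick", preserve_underscores=True
        )
        labels = {leaf.taxon.label for leaf in self._tree.leaf_node_iter()}
        for taxon, n in self.samples_per_taxon.items():
            if taxon not in labels:
                raise ValidationError(f"taxon {taxon!r} not in species tree")
            if n < 1:
                raise ValidationError(f"taxon {taxon!r} needs >= 1 sample")
        missing = labels - set(self.samples_per_taxon)
        if missing:
            raise ValidationError(f"no sample counts for taxa {sorted(missing)}")
        self._build_branches()
        for pulse in self.migration:
            d = self._branch_of_clade(pulse.donor)
            r = self._branch_of_clade(pulse.recipient)
            for b, role in ((d, "donor"), (r, "recipient")):
                lo, hi = self._age[b], self._parent_age[b]
                if not (lo <= pulse.time < hi):
                    raise ValidationError(
                        f"pulse time {pulse.time} outside {role} branch "
                        f"existence [{lo}, {hi})"
                    )

    # Branches are indexed by species-tree node; the branch above node i
    # exists over ages [age[i], age[parent(i)]).
    def _build_branches(self) -> None:
        nodes = list(self._tree.preorder_node_iter())
        self._nodes = nodes
        index = {id(n): i for i, n in enumerate(nodes)}
        n = len(nodes)
        self._age = np.zeros(n)
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                self._age[index[id(node)]] = 0.0
            else:
                self._age[index[id(node)]] = max(
                    self._age[index[id(c)]] + (c.edge.length or 0.0)
                    for c in node.child_nodes()
                )
        self._parent = np.full(n, -1, dtype=int)
        self._parent_age = np.full(n, np.inf)
        for i, node in enumerate(nodes):
            if node.parent_node is not None:
                p = index[id(node.parent_node)]
                self._parent[i] = p
                self._parent_age[i] = self._age[p]
        self._leaf_branch = {
            node.taxon.label: i for i, node in enumerate(nodes) if node.is_leaf()
        }
        self._clade_leaves = [
            frozenset(l.taxon.label for l in node.leaf_iter()) for node in nodes
        ]
        self._root_index = index[id(self._tree.seed_node)]

    def _branch_of_clade(self, spec) -> int:
        key = MigrationPulse._key(spec)
        for i, leaves in enumerate(self._clade_leaves):
            if leaves == key:
                return i
        raise ValidationError(f"no species-tree branch for clade {sorted(key)}")

    @property
    def taxa(self) -> list[str]:
        return [l.taxon.label for l in self._tree.leaf_node_iter()]

    def sample_ids(self) -> list[str]:
        return [
            f"{taxon}_{i + 1}"
            for taxon in self.taxa
            for i in range(self.samples_per_taxon[taxon])
        ]

    def tip_labels(self) -> list[str]:
        """Haploid gene-tree tip labels, grouped by sample."""
        if self.ploidy == 1:
            return self.sample_ids()
        return [
            f"{sample}|{chr(ord('a') + k)}"
            for sample in self.sample_ids()
            for k in range(self.ploidy)
        ]

    def population_map(self) -> PopulationMap:
        return PopulationMap(
            {
                f"{taxon}_{i + 1}": taxon
                for taxon in self.taxa
                for i in range(self.samples_per_taxon[taxon])
            }
        )


@dataclass
class MutationModel:
    """Infinite-sites mutation: expected SNPs per gene tree (Poisson)."""

    snps_per_tree: float = 20.0

    def __post_init__(self) -> None:
        if self.snps_per_tree <= 0:
            raise ValidationError("expected SNP count must be > 0")


@dataclass
class ScaffoldLayout:
    """Fixed-width coordinate blocks for gene trees across scaffolds."""

    block_bp: int = 10_000
    trees_per_scaffold: int = 50
    scaffold_prefix: str = "scaffold_"

    def scaffold_name(self, tree_index: int) -> str:
        return f"{self.scaffold_prefix}{tree_index // self.trees_per_scaffold + 1}"

    def block_start(self, tree_index: int) -> int:
        return (tree_index % self.trees_per_scaffold) * self.block_bp

    def scaffold_lengths(self, n_trees: int) -> dict[str, int]:
        out: dict[str, int] = {}
        for j in range(n_trees):
            name = self.scaffold_name(j)
            out[name] = max(out.get(name, 0), self.block_start(j) + self.block_bp)
        return out


# ---------------------------------------------------------------------------
# Gene-tree simulation


class _SimTree:
    """Lightweight gene tree: parent pointers + node times, tips 0..n-1."""

    __slots__ = ("parent", "time", "labels")

    def __init__(self, parent: np.ndarray, time: np.ndarray, labels: list[str]):
        self.parent = parent
        self.time = time
        self.labels = labels

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        tree = dendropy.Tree(
            taxon_namespace=taxon_namespace or dendropy.TaxonNamespace()
        )
        n = len(self.parent)
        nodes = [dendropy.Node() for _ in range(n)]
        for i, label in enumerate(self.labels):
            taxon = tree.taxon_namespace.require_taxon(label=label)
            nodes[i].taxon = taxon
        root = None
        for i in range(n):
            p = self.parent[i]
            if p < 0:
                root = nodes[i]
            else:
                nodes[p].add_child(nodes[i])
                nodes[i].edge.length = float(self.time[p] - self.time[i])
        tree.seed_node = root
        return tree


def _simulate_sim_tree(model: SpeciesTreeModel, rng: np.random.Generator) -> _SimTree:
    labels = model.tip_labels()
    n_tips = len(labels)
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int32)
    time = np.zeros(n_nodes)
    next_node = n_tips

    # lineages per species-tree branch
    per_branch: dict[int, list[int]] = {}
    tip = 0
    for taxon in model.taxa:
        b = model._leaf_branch[taxon]
        k = model.samples_per_taxon[taxon] * model.ploidy
        per_branch.setdefault(b, []).extend(range(tip, tip + k))
        tip += k

    # scheduled events: species-node merges and migration pulses
    events: list[tuple[float, int, str, object]] = []
    for i in range(len(model._nodes)):
        if model._age[i] > 0:
            events.append((model._age[i], 1, "merge", i))
    for pulse in model.migration:
        events.append((pulse.time, 0, "pulse", pulse))
    events.sort(key=lambda e: (e[0], e[1]))

    t_now = 0.0
    n_live = n_tips

    def coalesce_until(t_end: float) -> None:
        nonlocal t_now, next_node, n_live
        while True:
            branches = [b for b, lin in per_branch.items() if len(lin) >= 2]
            if not branches:
                t_now = t_end if np.isfinite(t_end) else t_now
                return
            rates = np.array(
                [len(per_branch[b]) * (len(per_branch[b]) - 1) / 2.0 for b in branches]
            )
            total = rates.sum()
            dt = rng.exponential(1.0 / total)
            if t_now + dt >= t_end:
                t_now = t_end
                return
            t_now += dt
            b = branches[rng.choice(len(branches), p=rates / total)]
            lin = per_branch[b]
            i, j = rng.choice(len(lin), size=2, replace=False)
            a, c = lin[i], lin[j]
            node = next_node
            next_node += 1
            parent[a] = parent[c] = node
            time[node] = t_now
            per_branch[b] = [x for x in lin if x not in (a, c)] + [node]
            n_live -= 1
            if n_live == 1:
                return

    for t_ev, _, kind, payload in events:
        coalesce_until(t_ev)
        if n_live == 1:
            break
        if kind == "merge":
            node_idx = payload
            children = [
                i for i in range(len(model._nodes)) if model._parent[i] == node_idx
            ]
            moved: list[int] = []
            for c in children:
                moved.extend(per_branch.pop(c, []))
            if moved:
                per_branch.setdefault(node_idx, []).extend(moved)
        else:
            pulse = payload
            d = model._branch_of_clade(pulse.donor)
            r = model._branch_of_clade(pulse.recipient)
            stay: list[int] = []
            jump: list[int] = []
            for lin in per_branch.get(r, []):
                (jump if rng.random() < pulse.fraction else stay).append(lin)
            if jump:
                per_branch[r] = stay
                per_branch.setdefault(d, []).extend(jump)
    coalesce_until(np.inf)
    return _SimTree(parent[:next_node], time[:next_node], labels)


def simulate_gene_trees(
    model: SpeciesTreeModel, n_trees: int, seed: int
) -> list[dendropy.Tree]:
    """Draw ``n_trees`` MSC gene trees; deterministic for a given seed."""
    if n_trees < 1:
        raise ValidationError("n_trees must be >= 1")
    rng = np.random.default_rng(seed)
    namespace = dendropy.TaxonNamespace()
    return [
        _simulate_sim_tree(model, rng).to_dendropy(namespace) for _ in range(n_trees)
    ]


# ---------------------------------------------------------------------------
# Mutation sprinkling


def _edge_masks(tree, tip_order: dict[str, int]) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge (length, descendant-tip boolean mask) for any tree form."""
    n_tips = len(tip_order)
    if isinstance(tree, _SimTree):
        n = len(tree.parent)
        masks = np.zeros((n, n_tips), dtype=bool)
        for i, label in enumerate(tree.labels):
            masks[i, tip_order[label]] = True
        lengths = np.zeros(n)
        order = np.argsort(tree.time)  # children before parents
        for i in order:
            p = tree.parent[i]
            if p >= 0:
                masks[p] |= masks[i]
                lengths[i] = tree.time[p] - tree.time[i]
        return lengths, masks
    # dendropy tree
    nodes = list(tree.postorder_node_iter())
    masks = np.zeros((len(nodes), n_tips), dtype=bool)
    lengths = np.zeros(len(nodes))
    index = {id(n): i for i, n in enumerate(nodes)}
    for i, node in enumerate(nodes):
        if node.is_leaf():
            masks[i, tip_order[node.taxon.label]] = True
        else:
            for c in node.child_nodes():
                masks[i] |= masks[index[id(c)]]
        if node.parent_node is not None:
            lengths[i] = node.edge.length or 0.0
    return lengths, masks


def _tip_order_and_samples(labels: list[str]) -> tuple[dict[str, int], list[str], int]:
    order = {label: i for i, label in enumerate(labels)}
    samples: list[str] = []
    for label in labels:
        s = label.split("|")[0]
        if not samples or samples[-1] != s:
            samples.append(s)
    ploidy = len(labels) // len(samples)
    if ploidy * len(samples) != len(labels) or ploidy not in (1, 2):
        raise ValidationError("tips do not pair into 1 or 2 copies per sample")
    return order, samples, ploidy


def _tree_labels(tree) -> list[str]:
    if isinstance(tree, _SimTree):
        return tree.labels
    return [l.taxon.label for l in tree.leaf_node_iter()]


def sprinkle_mutations(
    trees, model: MutationModel, layout: ScaffoldLayout, seed: int
) -> GenotypeMatrix:
    """Place infinite-sites SNPs on gene trees and emit diploid genotypes.

    Each tree gets a Poisson(``snps_per_tree``) number of SNPs, branches
    chosen proportionally to length; positions are drawn without
    replacement inside the tree's scaffold block.  Tip labels of the form
    ``sample|a`` / ``sample|b`` are paired into a diploid genotype.
    """
    trees = list(trees)
    if not trees:
        raise ValidationError("empty tree list")
    rng = np.random.default_rng(seed)
    labels0 = sorted(_tree_labels(trees[0]))
    canonical = _tree_labels(trees[0])
    tip_order, samples, ploidy = _tip_order_and_samples(canonical)

    scaffold_names: list[str] = []
    scaf_idx: list[np.ndarray] = []
    positions: list[np.ndarray] = []
    rows: list[np.ndarray] = []
    refs: list[np.ndarray] = []
    alts: list[np.ndarray] = []
    bases = np.array(list("ACGT"))

    for j, tree in enumerate(trees):
        if sorted(_tree_labels(tree)) != labels0:
            raise ValidationError("trees have inconsistent tip labels")
        lengths, masks = _edge_masks(tree, tip_order)
        usable = (lengths > 0) & ~masks.all(axis=1)
        n_mut = rng.poisson(model.snps_per_tree)
        n_mut = min(n_mut, layout.block_bp)  # infinite sites within the block
        if n_mut == 0 or not usable.any():
            continue
        probs = np.where(usable, lengths, 0.0)
        probs = probs / probs.sum()
        edge_idx = rng.choice(len(lengths), size=n_mut, p=probs)
        offs = np.sort(rng.choice(layout.block_bp, size=n_mut, replace=False))
        derived = masks[edge_idx]  # n_mut x n_tips
        if ploidy == 2:
            geno = derived[:, 0::2].astype(np.int8) + derived[:, 1::2].astype(np.int8)
        else:
            geno = 2 * derived.astype(np.int8)
        name = layout.scaffold_name(j)
        if name not in scaffold_names:
            scaffold_names.append(name)
        scaf_idx.append(np.full(n_mut, scaffold_names.index(name), dtype=np.int32))
        positions.append(layout.block_start(j) + offs + 1)
        rows.append(geno)
        ref = bases[rng.integers(0, 4, size=n_mut)]
        alt = bases[(np.char.find("ACGT", ref) + rng.integers(1, 4, size=n_mut)) % 4]
        refs.append(ref)
        alts.append(alt)

    n_samples = len(samples)
    if not rows:
        return GenotypeMatrix(
            scaffold_names=[],
            scaffold_index=np.empty(0, dtype=np.int32),
            positions=np.empty(0, dtype=np.int64),
            genotypes=np.empty((0, n_samples), dtype=np.int8),
            ref=np.empty(0, dtype="U1"),
            alt=np.empty(0, dtype="U1"),
            sample_ids=samples,
        )
    return GenotypeMatrix(
        scaffold_names=scaffold_names,
        scaffold_index=np.concatenate(scaf_idx),
        positions=np.concatenate(positions),
        genotypes=np.vstack(rows),
        ref=np.concatenate(refs),
        alt=np.concatenate(alts),
        sample_ids=samples,
    )


def simulate_dataset(
    model: SpeciesTreeModel,
    n_trees: int,
    mutation: MutationModel,
    layout: ScaffoldLayout,
    seed: int,
    return_trees: bool = False,
):
    """Gene trees + SNP matrix in one call (fast path without dendropy).

    Returns ``(matrix, trees)`` where *trees* is the dendropy tree list
    when ``return_trees`` is set, else ``None``.
    """
    rng = np.random.default_rng(seed)
    sim_trees = [_simulate_sim_tree(model, rng) for _ in range(n_trees)]
    matrix = sprinkle_mutations(
        sim_trees, mutation, layout, seed=int(rng.integers(2**31))
    )
    trees = None
    if return_trees:
        namespace = dendropy.TaxonNamespace()
        trees = [t.to_dendropy(namespace) for t in sim_trees]
    return matrix, trees


def random_cds_intervals(
    layout: ScaffoldLayout,
    n_trees: int,
    density: float,
    seed: int,
    mean_cds_bp: int = 1_500,
) -> dict[str, IntervalSet]:
    """Random CDS intervals at a target genome-wide genic density."""
    if not 0.0 < density < 1.0:
        raise ValidationError("density must be in (0, 1)")
    rng = np.random.default_rng(seed)
    lengths = layout.scaffold_lengths(n_trees)
    out: dict[str, IntervalSet] = {}
    for scaffold, L in lengths.items():
        target = density * L
        ivs: list[tuple[int, int]] = []
        covered = 0.0
        while covered < target:
            size = max(90, int(rng.exponential(mean_cds_bp)))
            start = int(rng.integers(0, max(1, L - size)))
            ivs.append((start, min(start + size, L)))
            covered += size
        out[scaffold] = IntervalSet(scaffold=scaffold, intervals=ivs)
    return out


# ---------------------------------------------------------------------------
# Loss-of-function CDS fixtures


@dataclass
class LofSpec:
    """One injected mutation for a CDS fixture copy.

    ``position`` is a 0-based nucleotide coordinate in the reference CDS;
    ``length`` applies to indels.  Frameshift indels must not be a
    multiple of 3; deletions below ``large_deletion_min`` (checked in
    :func:`make_cds_fixture`) are not "large".
    """

    kind: str
    position: int
    length: int = 0
    zygosity: str = "hom"

    KINDS = (
        "large_deletion",
        "frameshift_insertion",
        "frameshift_deletion",
        "premature_stop_substitution",
        "domain_substitution",
        "inframe_deletion",
    )

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValidationError(f"unknown LOF kind {self.kind!r}")
        if self.kind in ("frameshift_insertion", "frameshift_deletion"):
            if self.length % 3 == 0:
                raise ValidationError("frameshift indel length must not be %3 == 0")
        if self.kind == "inframe_deletion" and self.length % 3 != 0:
            raise ValidationError("in-frame deletion length must be %3 == 0")
        if self.zygosity not in ("hom", "het"):
            raise ValidationError("zygosity must be 'hom' or 'het'")


def random_cds(n_codons: int, seed: int) -> str:
    """Random CDS: ATG start, no internal stops, TAA terminator."""
    rng = np.random.default_rng(seed)
    sense = [
        a + b + c
        for a, b, c in itertools.product("ACGT", repeat=3)
        if a + b + c not in STOP_CODONS and a + b + c != "ATG"
    ]
    body = [sense[int(i)] for i in rng.integers(0, len(sense), size=n_codons - 2)]
    return "ATG" + "".join(body) + "TAA"


def _codon_to_stop(codon: str) -> str:
    """A stop codon reachable from *codon*, preferring a one-base change."""
    for stop in STOP_CODONS:
        if sum(a != b for a, b in zip(codon, stop)) == 1:
            return stop
    return "TAA"


def _nonsyn_substitution(codon: str, rng: np.random.Generator) -> tuple[int, str]:
    """(offset, new base) making a nonsynonymous, non-stop change."""
    from Bio.Seq import Seq

    aa = str(Seq(codon).translate())
    options = []
    for off in range(3):
        for base in "ACGT":
            if base == codon[off]:
                continue
            mutant = codon[:off] + base + codon[off + 1 :]
            if mutant in STOP_CODONS:
                continue
            if str(Seq(mutant).translate()) != aa:
                options.append((off, base))
    if not options:
        raise ValidationError(f"codon {codon} admits no nonsynonymous change")
    return options[int(rng.integers(0, len(options)))]


def make_cds_fixture(
    reference_cds: str,
    exon_boundaries: list[tuple[int, int]],
    domains: list[tuple[str, int, int]],
    specs: list[LofSpec],
    seed: int,
    n_clean: int = 1,
    large_deletion_min: int = 100,
) -> CdsAlignmentSet:
    """Aligned CDS copies, one per spec, each carrying exactly its mutation.

    The returned alignment has the reference row first; insertion specs
    add gap columns to every other row.  Heterozygous substitutions are
    encoded as IUPAC ambiguity codes.  Copy names encode the injected
    mutation kind so downstream truth is recoverable.
    """
    from Bio.Seq import Seq

    ref = reference_cds.upper()
    if len(ref) % 3 != 0:
        raise ValidationError("reference CDS length must be a multiple of 3")
    protein = str(Seq(ref).translate())
    if "*" in protein[:-1]:
        raise ValidationError("reference CDS has an internal stop codon")
    for name, a, b in domains:
        if not (0 <= a < b <= len(protein)):
            raise ValidationError(f"domain {name!r} outside protein length")
    rng = np.random.default_rng(seed)

    # Gather insertion columns: (reference position, length, inserted seq)
    insertions: list[tuple[int, int, str, int]] = []
    for k, spec in enumerate(specs):
        if not 0 <= spec.position < len(ref):
            raise ValidationError(f"spec {k}: position {spec.position} outside CDS")
        if spec.kind == "large_deletion" and spec.length < large_deletion_min:
            raise ValidationError(
                f"spec {k}: large_deletion shorter than {large_deletion_min} bp"
            )
        if spec.kind == "frameshift_insertion":
            bases = "".join(
                "ACGT"[int(i)] for i in rng.integers(0, 4, size=spec.length)
            )
            insertions.append((spec.position, spec.length, bases, k))
    insertions.sort()

    # Column map: reference coordinate -> alignment column
    n_cols = len(ref) + sum(length for _, length, _, _ in insertions)
    ref_row = []
    col_of_refpos = np.zeros(len(ref) + 1, dtype=int)
    ins_cols: dict[int, tuple[int, str]] = {}  # spec index -> (start col, seq)
    pos = 0
    ins_iter = iter(insertions)
    nxt = next(ins_iter, None)
    for p in range(len(ref) + 1):
        while nxt is not None and nxt[0] == p:
            ins_cols[nxt[3]] = (len(ref_row), nxt[2])
            ref_row.extend("-" * nxt[1])
            nxt = next(ins_iter, None)
        col_of_refpos[p] = len(ref_row)
        if p < len(ref):
            ref_row.append(ref[p])
    assert len(ref_row) == n_cols

    def blank_copy() -> list[str]:
        row = list(ref_row)
        return row

    copies: dict[str, str] = {}
    for k, spec in enumerate(specs):
        row = blank_copy()
        if spec.kind in ("large_deletion", "frameshift_deletion", "inframe_deletion"):
            end = min(spec.position + spec.length, len(ref))
            for p in range(spec.position, end):
                row[col_of_refpos[p]] = "-"
        elif spec.kind == "frameshift_insertion":
            start, bases = ins_cols[k]
            for i, b in enumerate(bases):
                row[start + i] = b
        elif spec.kind == "premature_stop_substitution":
            cstart = (spec.position // 3) * 3
            codon = ref[cstart : cstart + 3]
            stop = _codon_to_stop(codon)
            for off in range(3):
                if stop[off] != codon[off]:
                    col = col_of_refpos[cstart + off]
                    if spec.zygosity == "het":
                        row[col] = _IUPAC_PAIR[frozenset({codon[off], stop[off]})]
                    else:
                        row[col] = stop[off]
        elif spec.kind == "domain_substitution":
            cstart = (spec.position // 3) * 3
            codon = ref[cstart : cstart + 3]
            off, base = _nonsyn_substitution(codon, rng)
            col = col_of_refpos[cstart + off]
            if spec.zygosity == "het":
                row[col] = _IUPAC_PAIR[frozenset({codon[off], base})]
            else:
                row[col] = base
        copies[f"lof{k + 1}_{spec.kind}"] = "".join(row)
    for i in range(n_clean):
        copies[f"clean_{i + 1}"] = "".join(blank_copy())

    return CdsAlignmentSet(
        reference_name="reference",
        reference_row="".join(ref_row),
        copies=copies,
        exon_boundaries=list(exon_boundaries),
        domains=list(domains),
    )


def sample_level_trees(trees) -> list[dendropy.Tree]:
    """Collapse haploid gene trees to one tip per diploid sample.

    Keeps the first haploid copy (``sample|a``) of every sample and
    relabels it to the sample id, emulating the sample-level window
    trees estimated from consensus sequences.  Trees without ``|``
    labels are returned unchanged.
    """
    out = []
    for t in trees:
        keep = [l.taxon.label for l in t.leaf_node_iter() if l.taxon.label.endswith("|a")]
        if not keep:
            out.append(t)
            continue
        sub = t.extract_tree_with_taxa_labels(keep)
        nwk = sub.as_string(schema="newick", suppress_rooting=True).replace("|a", "")
        out.append(
            dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
        )
    return out


# ---------------------------------------------------------------------------
# Dataset writers


def write_dataset(
    outdir,
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    layout: ScaffoldLayout,
    n_trees: int,
    gene_trees=None,
    cds: dict[str, IntervalSet] | None = None,
) -> dict[str, str]:
    """Write VCF + popmap TSV + BED + Newick so downstream stages consume
    the same formats as real data.  Returns the path manifest."""
    import os

    from . import io as _io

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    vcf = os.path.join(outdir, "simulated.vcf")
    _io.write_vcf(matrix, vcf, scaffold_lengths=layout.scaffold_lengths(n_trees))
    paths["vcf"] = vcf
    pm = os.path.join(outdir, "popmap.tsv")
    popmap.to_tsv(pm)
    paths["popmap"] = pm
    if cds is not None:
        bed = os.path.join(outdir, "cds.bed")
        with open(bed, "w") as fh:
            for scaffold, ivset in cds.items():
                for s, e in ivset.intervals:
                    fh.write(f"{scaffold}\t{s}\t{e}\n")
        paths["cds_bed"] = bed
    if gene_trees is not None:
        nwk = os.path.join(outdir, "gene_trees.nwk")
        _io.write_trees(sample_level_trees(gene_trees), nwk)
        paths["gene_trees"] = nwk
    return paths
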