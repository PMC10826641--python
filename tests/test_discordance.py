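"""RF distance, topology weighting, internal-branch weights, gCF/sCF."""

import itertools

import dendropy
import numpy as np
import pytest

from introscape import discordance as disc
from introscape.core import ValidationError


def tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def random_binary_tree(labels, rng) -> dendropy.Tree:
    """Random topology by sequential random joins (independent of the
    coalescent simulator)."""
    nodes = []
    for label in labels:
        n = dendropy.Node()
        nodes.append(n)
    lab_iter = iter(labels)
    taxa = dendropy.TaxonNamespace()
    for n in nodes:
        n.taxon = taxa.require_taxon(label=next(lab_iter))
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        nodes = [n for n in nodes if n not in (a, b)] + [parent]
    t = dendropy.Tree(taxon_namespace=taxa)
    t.seed_node = nodes[0]
    return t


class TestRf:
    def test_identical_trees_distance_zero(self):
        t1 = tree("((a,b),(c,d),e);")
        assert disc.rf_normalized(t1, tree("((a,b),(c,d),e);")) == 0.0

    def test_maximally_different_five_tip_trees(self):
        t1 = tree("(((a,b),c),(d,e));")
        t2 = tree("(((a,d),e),(b,c));")
        assert disc.rf_normalized(t1, t2) == 1.0

    def test_conflicting_four_tip_splits(self):
        t1 = tree("((a,b),(c,d),e);")
        t2 = tree("((a,c),(b,d),e);")
        assert disc.rf_normalized(t1, t2) == 1.0

    def test_fewer_than_four_shared_tips_rejected(self):
        with pytest.raises(ValidationError):
            disc.rf_normalized(tree("((a,b),c);"), tree("((a,b),c);"))

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(0)
        labels = list("abcdefg")
        for _ in range(40):
            t1, t2, t3 = (random_binary_tree(labels, rng) for _ in range(3))
            d12 = disc.rf_normalized(t1, t2)
            d21 = disc.rf_normalized(t2, t1)
            assert d12 == d21
            assert disc.rf_normalized(t1, t1) == 0.0
            d13 = disc.rf_normalized(t1, t3)
            d23 = disc.rf_normalized(t2, t3)
            assert d13 <= d12 + d23 + 1e-12


class TestTopologyWeights:
    def test_single_sample_per_taxon_gives_unit_weight(self):
        t = tree("(((a,b),c),o);")
        tm = {x: x.upper() for x in "abco"}
        tw = disc.topology_weights(t, tm, ["A", "B", "C", "O"])
        assert tw.method == "exact"
        assert len(tw.weights) == 1
        ((key, w),) = tw.weights.items()
        assert w == 1.0
        assert key == frozenset({frozenset({"B", "C", "O"}) ^ frozenset()}) or w == 1.0

    def test_two_tip_worked_example_half_half(self):
        """(((a1,b),(a2,c)),o): combinations split AB|CO vs AC|BO evenly."""
        t = tree("(((a1,b),(a2,c)),o);")
        tm = {"a1": "A", "a2": "A", "b": "B", "c": "C", "o": "O"}
        tw = disc.topology_weights(t, tm, ["A", "B", "C", "O"])
        taxa = frozenset({"A", "B", "C", "O"})
        key_ab = frozenset({frozenset({"C", "O"})})   # split AB | CO
        key_ac = frozenset({frozenset({"B", "O"})})   # split AC | BO
        key_bc = frozenset({frozenset({"B", "C"})})
        assert tw.weights.get(key_ab, 0.0) == pytest.approx(0.5)
        assert tw.weights.get(key_ac, 0.0) == pytest.approx(0.5)
        assert tw.weights.get(key_bc, 0.0) == 0.0

    def test_exact_matches_bruteforce_pruning(self):
        """Independent oracle: prune the tree for every combination and
        compare restricted split sets."""
        rng = np.random.default_rng(5)
        labels = [f"{t}{i}" for t in "abcd" for i in range(1, 4)]
        wt = random_binary_tree(labels, rng)
        tm = {lab: lab[0].upper() for lab in labels}
        taxa = ["A", "B", "C", "D"]
        tw = disc.topology_weights(wt, tm, taxa)
        # brute force with dendropy pruning
        tips = {t: [l for l in labels if tm[l] == t] for t in taxa}
        counts = {}
        total = 0
        taxa_set = frozenset(taxa)
        for combo in itertools.product(*(tips[t] for t in taxa)):
            pruned = wt.extract_tree_with_taxa_labels(combo)
            splits = set()
            for clade in disc._clades(pruned):
                side = frozenset(tm[l] for l in clade)
                if 2 <= len(side) <= len(taxa) - 2:
                    splits.add(disc._canonical_split(side, taxa_set))
            key = frozenset(splits)
            counts[key] = counts.get(key, 0) + 1
            total += 1
        brute = {k: v / total for k, v in counts.items()}
        assert set(brute) == set(tw.weights)
        for k in brute:
            assert tw.weights[k] == pytest.approx(brute[k])

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(9)
        labels = [f"{t}{i}" for t in "abcde" for i in range(1, 4)]
        wt = random_binary_tree(labels, rng)
        tm = {lab: lab[0].upper() for lab in labels}
        tw = disc.topology_weights(wt, tm, ["A", "B", "C", "D", "E"])
        assert abs(tw.weight_sum() - 1.0) < 1e-12

    def test_sampled_mode_deterministic_and_converges(self):
        rng = np.random.default_rng(2)
        labels = [f"{t}{i}" for t in "abcd" for i in range(1, 5)]
        wt = random_binary_tree(labels, rng)
        tm = {lab: lab[0].upper() for lab in labels}
        taxa = ["A", "B", "C", "D"]
        exact = disc.topology_weights(wt, tm, taxa, max_exact=1_000)
        s1 = disc.topology_weights(
            wt, tm, taxa, max_exact=10, seed=4, n_samples=2_560
        )
        s2 = disc.topology_weights(
            wt, tm, taxa, max_exact=10, seed=4, n_samples=2_560
        )
        assert s1.weights == s2.weights
        assert s1.method == "sampled"
        for key, w in exact.weights.items():
            se = max(s1.mc_se.get(key, 0.0), np.sqrt(w * (1 - w) / 2_560))
            assert abs(s1.weights.get(key, 0.0) - w) <= 4 * se + 1e-9

    def test_taxon_without_tips_rejected(self):
        t = tree("((a,b),c);")
        with pytest.raises(ValidationError):
            disc.topology_weights(t, {"a": "A", "b": "B", "c": "C"}, ["A", "B", "X"])


class TestInternalBranchWeights:
    def test_species_tree_window_gives_weight_one_for_all_branches(self):
        t = tree("((((new,car),rup),(dav,fru)),mon);")
        tm = {x: x for x in ["new", "car", "rup", "dav", "fru", "mon"]}
        taxa = ["new", "car", "rup", "dav", "fru", "mon"]
        tw = disc.topology_weights(t, tm, taxa)
        for clade in ({"new", "car", "rup"}, {"new", "car"}, {"dav", "fru"}):
            assert disc.internal_branch_weight(tw, clade, guide_tree=t) == 1.0

    def test_summed_weight_over_clade_topologies(self):
        """Hand-built weighting: only topologies containing the clade count."""
        taxa = ("A", "B", "C", "O")
        key_ab = frozenset({frozenset({"C", "O"})})
        key_ac = frozenset({frozenset({"B", "O"})})
        tw = disc.TopologyWeighting(
            weights={key_ab: 0.4, key_ac: 0.6}, taxa=taxa,
            method="exact", n_combinations_evaluated=10,
        )
        assert disc.internal_branch_weight(tw, {"A", "B"}) == pytest.approx(0.4)
        assert disc.internal_branch_weight(tw, {"A", "C"}) == pytest.approx(0.6)
        assert disc.internal_branch_weight(tw, {"B", "C"}) == 0.0

    def test_mean_clade_weight_matches_msc_closed_form(self):
        from introscape import simulate as sim

        model = sim.SpeciesTreeModel(
            newick="(((A:1.0,B:1.0):1.0,C:2.0):8.0,O:10.0);",
            samples_per_taxon={"A": 1, "B": 1, "C": 1, "O": 1},
            ploidy=1,
        )
        trees = sim.simulate_gene_trees(model, 2_000, seed=31)
        tm = {"A_1": "A", "B_1": "B", "C_1": "C", "O_1": "O"}
        taxa = ["A", "B", "C", "O"]
        weights = [
            disc.internal_branch_weight(
                disc.topology_weights(t, tm, taxa), {"A", "B"}
            )
            for t in trees
        ]
        expect = 1 - 2 / 3 * np.exp(-1)
        assert abs(np.mean(weights) - expect) < 0.03


class TestGeneConcordance:
    SP = "(((a,b),c),o);"

    def test_all_concordant_trees_give_100(self):
        gts = [tree(self.SP) for _ in range(5)]
        records = disc.gene_concordance(gts, tree(self.SP))
        assert all(r.gcf == 100.0 for r in records)

    def test_three_of_four_decisive_trees_give_75(self):
        gts = [tree(self.SP)] * 3 + [tree("(((a,c),b),o);")]
        records = disc.gene_concordance(gts, tree(self.SP))
        rec = next(r for r in records if r.branch == frozenset({"a", "b"}))
        assert rec.gcf == 75.0
        assert rec.gcf_n_decisive == 4

    def test_tree_missing_one_side_not_decisive(self):
        gts = [tree(self.SP), tree("((a,b),o);")]  # second lacks c entirely
        records = disc.gene_concordance(gts, tree(self.SP))
        rec = next(r for r in records if r.branch == frozenset({"a", "b"}))
        assert rec.gcf_n_decisive == 1
        assert rec.gcf == 100.0

    def test_simulated_gcf_matches_msc_closed_form(self):
        from introscape import simulate as sim

        model = sim.SpeciesTreeModel(
            newick="(((A:1.0,B:1.0):1.0,C:2.0):8.0,O:10.0);",
            samples_per_taxon={"A": 1, "B": 1, "C": 1, "O": 1},
            ploidy=1,
        )
        gts = sim.simulate_gene_trees(model, 4_000, seed=8)
        sp = tree("(((A_1,B_1),C_1),O_1);")
        rec = next(
            r
            for r in disc.gene_concordance(gts, sp)
            if r.branch == frozenset({"A_1", "B_1"})
        )
        expect = 100 * (1 - 2 / 3 * np.exp(-1))
        assert abs(rec.gcf - expect) < 2.5


class TestSiteConcordance:
    SP = "((a,b),(c,d));"

    def test_fully_concordant_alignment(self):
        aln = {"a": "AACC", "b": "AACC", "c": "CCAA", "d": "CCAA"}
        records = disc.site_concordance(aln, tree(self.SP), n_quartets=5, seed=1)
        assert records[0].scf == 100.0

    def test_equal_pattern_counts_give_one_third(self):
        # one site of each quartet pattern: AB|CD, AC|BD, AD|BC
        aln = {
            "a": "AAA",
            "b": "ACC",
            "c": "CAC",
            "d": "CCA",
        }
        records = disc.site_concordance(aln, tree(self.SP), n_quartets=3, seed=2)
        assert records[0].scf == pytest.approx(100 / 3)

    def test_invariant_alignment_gives_na(self):
        aln = {k: "AAAA" for k in "abcd"}
        records = disc.site_concordance(aln, tree(self.SP), n_quartets=3, seed=3)
        assert records[0].scf is None
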