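"""MSC simulator: topology frequencies, migration pulses, mutations, fixtures."""

import numpy as np
import pytest

from introscape import simulate as sim
from introscape.core import MISSING, ValidationError

TRIPLET = "((A:1.0,B:1.0):1.0,C:2.0);"


def _cherry(tree) -> frozenset:
    """Tip-label pair that coalesces first in a rooted 3-tip tree."""
    for child in tree.seed_node.child_nodes():
        leaves = frozenset(l.taxon.label for l in child.leaf_iter())
        if len(leaves) == 2:
            return leaves
    raise AssertionError("unresolved triplet")


def triplet_model(t=1.0, ploidy=1):
    return sim.SpeciesTreeModel(
        newick=f"((A:1.0,B:1.0):{t},C:{1.0 + t});",
        samples_per_taxon={"A": 1, "B": 1, "C": 1},
        ploidy=ploidy,
    )


class TestGeneTrees:
    def test_triplet_frequencies_match_closed_form(self):
        """Concordance ~ 1 - (2/3)e^-t; discordants each ~ (1/3)e^-t."""
        trees = sim.simulate_gene_trees(triplet_model(t=1.0), 4000, seed=11)
        conc = sum(_cherry(t) == frozenset({"A_1", "B_1"}) for t in trees) / 4000
        expect = 1 - 2 / 3 * np.exp(-1)
        assert abs(conc - expect) < 3 * np.sqrt(expect * (1 - expect) / 4000)

    def test_long_internal_branch_gives_full_concordance(self):
        trees = sim.simulate_gene_trees(triplet_model(t=50.0), 300, seed=3)
        assert all(_cherry(t) == frozenset({"A_1", "B_1"}) for t in trees)

    def test_same_seed_reproduces_tree_list(self):
        model = triplet_model()
        a = sim.simulate_gene_trees(model, 20, seed=9)
        b = sim.simulate_gene_trees(model, 20, seed=9)
        assert [t.as_string(schema="newick") for t in a] == [
            t.as_string(schema="newick") for t in b
        ]

    def test_matches_msprime_oracle_on_triplet(self):
        """Independent coalescent implementation agrees on discordance."""
        msprime = pytest.importorskip("msprime")
        demography = msprime.Demography()
        for pop in ("A", "B", "C", "AB", "ABC"):
            # haploid samples coalesce at rate 1/Ne: Ne=1 is coalescent units
            demography.add_population(name=pop, initial_size=1.0)
        demography.add_population_split(time=1.0, derived=["A", "B"], ancestral="AB")
        demography.add_population_split(time=2.0, derived=["AB", "C"], ancestral="ABC")
        n = 3000
        conc_ms = 0
        reps = msprime.sim_ancestry(
            samples={"A": 1, "B": 1, "C": 1},
            demography=demography,
            ploidy=1,
            num_replicates=n,
            random_seed=17,
        )
        for ts in reps:
            tree = ts.first()
            conc_ms += tree.mrca(0, 1) != tree.root
        mine = sim.simulate_gene_trees(triplet_model(t=1.0), n, seed=17)
        conc_me = sum(_cherry(t) == frozenset({"A_1", "B_1"}) for t in mine)
        se = np.sqrt(2 * 0.75 * 0.25 / n)
        assert abs(conc_ms / n - conc_me / n) < 4 * se

    def test_migration_needs_valid_time_and_fraction(self):
        with pytest.raises(ValidationError):
            sim.MigrationPulse(donor="A", recipient="B", time=0.5, fraction=1.5)
        with pytest.raises(ValidationError):
            sim.SpeciesTreeModel(
                newick=TRIPLET,
                samples_per_taxon={"A": 1, "B": 1, "C": 1},
                # C's branch ends at age 2 but A's tip branch ends at age 1
                migration=[
                    sim.MigrationPulse(donor="C", recipient="A", time=1.5, fraction=0.1)
                ],
            )

    def test_full_pulse_moves_all_recipients(self):
        """fraction=1 from C into B makes B coalesce with C, never with A."""
        model = sim.SpeciesTreeModel(
            newick="((A:1.0,B:1.0):5.0,C:6.0);",
            samples_per_taxon={"A": 1, "B": 1, "C": 1},
            ploidy=1,
            migration=[
                sim.MigrationPulse(donor="C", recipient="B", time=0.5, fraction=1.0)
            ],
        )
        trees = sim.simulate_gene_trees(model, 200, seed=2)
        frac_bc = sum(_cherry(t) == frozenset({"B_1", "C_1"}) for t in trees) / 200
        assert frac_bc > 0.95  # only pre-split coalescence with C is possible


class TestMutations:
    def test_mutation_marks_exactly_the_subtended_tips(self):
        """A clade's derived allele appears in exactly its samples."""
        model = sim.SpeciesTreeModel(
            newick="((A:1.0,B:1.0):2.0,C:3.0);",
            samples_per_taxon={"A": 2, "B": 2, "C": 2},
        )
        matrix, _ = sim.simulate_dataset(
            model, 30, sim.MutationModel(10), sim.ScaffoldLayout(), seed=21
        )
        # every site's derived set is a clade of some gene tree: at minimum
        # the allele-count coding must be consistent diploid 0/1/2
        assert set(np.unique(matrix.genotypes)) <= {0, 1, 2}
        assert matrix.is_variant().all()

    def test_total_snp_count_poisson_around_expectation(self):
        model = triplet_model(ploidy=2)
        totals = []
        for s in range(30):
            m, _ = sim.simulate_dataset(
                model, 10, sim.MutationModel(10.0), sim.ScaffoldLayout(), seed=s
            )
            totals.append(m.n_sites)
        mean = np.mean(totals)
        # Poisson(100) per replicate: mean of 30 has SE ~ sqrt(100/30)
        assert abs(mean - 100) < 4 * np.sqrt(100 / 30)

    def test_zero_length_branches_never_mutated_and_positions_sorted(self):
        import dendropy

        # star-ish tree with one zero branch: tips a,b at 0-length cherry
        tree = dendropy.Tree.get(
            data="((a:0.0,b:1.0):1.0,c:2.0);", schema="newick",
            preserve_underscores=True,
        )
        layout = sim.ScaffoldLayout(block_bp=1000)
        matrix = sim.sprinkle_mutations(
            [tree], sim.MutationModel(50), layout, seed=4
        )
        # tip a sits on a zero-length branch: it can only carry derived
        # alleles together with b (via the cherry's parent edge never --
        # that edge subtends both a and b)
        col_a = matrix.sample_ids.index("a")
        col_b = matrix.sample_ids.index("b")
        only_a = (matrix.genotypes[:, col_a] > 0) & (matrix.genotypes[:, col_b] == 0)
        assert not only_a.any()
        assert (np.diff(matrix.positions) > 0).all()

    def test_deterministic_given_seed(self):
        model = triplet_model(ploidy=2)
        a, _ = sim.simulate_dataset(model, 5, sim.MutationModel(8), sim.ScaffoldLayout(), seed=3)
        b, _ = sim.simulate_dataset(model, 5, sim.MutationModel(8), sim.ScaffoldLayout(), seed=3)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.positions, b.positions)

    def test_empty_tree_list_rejected(self):
        with pytest.raises(ValidationError):
            sim.sprinkle_mutations([], sim.MutationModel(5), sim.ScaffoldLayout(), 0)


class TestCdsFixture:
    def test_insertion_fixture_gaps_the_reference_row(self):
        ref = sim.random_cds(100, seed=1)
        spec = sim.LofSpec(kind="frameshift_insertion", position=90, length=4)
        aln = sim.make_cds_fixture(ref, [(0, 150), (150, 300)], [], [spec], seed=2)
        copy = aln.copies["lof1_frameshift_insertion"]
        i = aln.reference_row.index("----")
        assert "-" not in copy
        assert set(copy[i : i + 4]) <= set("ACGT")
        assert aln.copies["clean_1"][i : i + 4] == "----"

    def test_large_deletion_removes_second_exon(self):
        ref = sim.random_cds(300, seed=5)  # 900 bp
        exons = [(0, 200), (200, 650), (650, 900)]
        spec = sim.LofSpec(kind="large_deletion", position=190, length=500)
        aln = sim.make_cds_fixture(ref, exons, [], [spec], seed=6)
        row = aln.copies["lof1_large_deletion"]
        assert row[190:690] == "-" * 500
        from introscape.lof import detect_indels

        events, _ = detect_indels(aln, "lof1_large_deletion")
        dele = [e for e in events if e.kind == "large_deletion"][0]
        assert 2 in dele.exons

    def test_empty_spec_list_gives_identical_copies(self):
        ref = sim.random_cds(50, seed=7)
        aln = sim.make_cds_fixture(ref, [(0, 150)], [], [], seed=8, n_clean=3)
        assert all(row == aln.reference_row for row in aln.copies.values())

    def test_het_substitution_encoded_as_iupac(self):
        ref = sim.random_cds(60, seed=9)
        spec = sim.LofSpec(
            kind="premature_stop_substitution", position=60, zygosity="het"
        )
        aln = sim.make_cds_fixture(ref, [(0, 180)], [], [spec], seed=10)
        row = aln.copies["lof1_premature_stop_substitution"]
        assert any(ch in "RYSWKM" for ch in row)

    def test_frameshift_spec_rejects_multiple_of_three(self):
        with pytest.raises(ValidationError):
            sim.LofSpec(kind="frameshift_insertion", position=10, length=6)
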