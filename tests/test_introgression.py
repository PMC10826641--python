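"""Site patterns, D, jackknife, f4-ratio, f_dM, trios and f-branch."""

import dendropy
import numpy as np
import pytest

from introscape import introgression as intro
from introscape import simulate as sim
from introscape.core import PopulationMap, ValidationError
from tests.conftest import make_matrix

FOUR_POPS = PopulationMap({"smp1": "P1", "smp2": "P2", "smp3": "P3", "smp4": "O"})
TRIO = ("P1", "P2", "P3", "O")


def freq_matrix(patterns):
    """Matrix of single-diploid populations hitting given frequencies.

    Each pattern is (p1, p2, p3, p4) with values in {0, 0.5, 1}.
    """
    rows = [[int(round(2 * p)) for p in pat] for pat in patterns]
    return make_matrix(rows)


class TestSitePatterns:
    def test_pure_abba_site(self):
        s = intro.site_patterns(freq_matrix([(0, 1, 1, 0)]), FOUR_POPS, TRIO)
        assert (s.sum_abba, s.sum_baba) == (1.0, 0.0)

    def test_pure_baba_site(self):
        s = intro.site_patterns(freq_matrix([(1, 0, 1, 0)]), FOUR_POPS, TRIO)
        assert (s.sum_abba, s.sum_baba) == (0.0, 1.0)

    def test_mixed_frequency_sums(self):
        s = intro.site_patterns(
            freq_matrix([(0, 1, 1, 0), (0.5, 0.5, 0.5, 0)]), FOUR_POPS, TRIO
        )
        assert s.sum_abba == pytest.approx(1.125)
        assert s.sum_baba == pytest.approx(0.125)
        assert intro.d_statistic(s) == pytest.approx(0.8)

    def test_overlapping_populations_rejected(self):
        pm = PopulationMap({"smp1": "P1", "smp2": "P2", "smp3": "P3", "smp4": "P1"})
        with pytest.raises(ValidationError):
            intro.site_patterns(freq_matrix([(0, 1, 1, 0)]), pm, ("P1", "P2", "P3", "P1"))


class TestDStatistic:
    def test_limits(self):
        assert intro.d_statistic(intro.SitePatternSums(1.0, 1.0)) == 0.0
        assert intro.d_statistic(intro.SitePatternSums(2.0, 0.0)) == 1.0
        assert np.isnan(intro.d_statistic(intro.SitePatternSums(0.0, 0.0)))

    def test_antisymmetry_under_p1_p2_swap(self):
        rng = np.random.default_rng(1)
        pats = rng.choice([0, 0.5, 1], size=(50, 4))
        m = freq_matrix(pats)
        d_ab = intro.d_statistic(intro.site_patterns(m, FOUR_POPS, TRIO))
        d_ba = intro.d_statistic(
            intro.site_patterns(m, FOUR_POPS, ("P2", "P1", "P3", "O"))
        )
        assert d_ab == pytest.approx(-d_ba)
        assert abs(d_ab) <= 1.0


class TestJackknife:
    def test_two_block_se_matches_hand_formula(self):
        """Blocks of opposing pure patterns: D=0, delete-one D = -/+1."""
        m = freq_matrix([(0, 1, 1, 0)] * 2 + [(1, 0, 1, 0)] * 2)
        d, z, p, degenerate = intro.jackknife(m, FOUR_POPS, TRIO, n_blocks=2)
        # hand: D_full = 0; D_{-1} = -1, D_{-2} = +1, mean 0
        # SE^2 = (B-1)/B * sum((D_loo - mean)^2) = 1/2 * 2 = 1
        assert d == 0.0
        assert not degenerate
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_identical_blocks_are_degenerate(self):
        m = freq_matrix([(0, 1, 1, 0)] * 8)
        d, z, p, degenerate = intro.jackknife(m, FOUR_POPS, TRIO, n_blocks=4)
        assert d == 1.0 and degenerate

    def test_too_few_informative_sites_rejected(self):
        m = freq_matrix([(0, 1, 1, 0)] * 3)
        with pytest.raises(ValidationError):
            intro.jackknife(m, FOUR_POPS, TRIO, n_blocks=5)


class TestF4Ratio:
    def test_half_admixed_single_site(self):
        m = freq_matrix([(0, 0.5, 1, 0)])
        assert intro.f4_ratio(m, FOUR_POPS, TRIO) == pytest.approx(0.5)

    def test_p2_equal_p3_gives_one(self):
        rng = np.random.default_rng(2)
        p13 = rng.choice([0, 0.5, 1], size=(30, 2))
        pats = [(a, c, c, 0) for a, c in p13]
        m = freq_matrix(pats)
        assert intro.f4_ratio(m, FOUR_POPS, TRIO) == pytest.approx(1.0)

    def test_p2_equal_p1_gives_zero(self):
        pats = [(0.5, 0.5, 1, 0), (0, 0, 0.5, 0), (1, 1, 0.5, 0)]
        m = freq_matrix(pats)
        assert intro.f4_ratio(m, FOUR_POPS, TRIO) == pytest.approx(0.0)


class TestFdm:
    def test_single_site_extremes(self):
        assert intro.fdm_single_window(np.array([[0.0, 1, 1, 0]])) == pytest.approx(1.0)
        assert intro.fdm_single_window(np.array([[1.0, 0, 1, 0]])) == pytest.approx(-1.0)

    def test_antisymmetry_and_bound_on_random_windows(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = rng.random((rng.integers(2, 30), 4))
            f = intro.fdm_single_window(p)
            f_swapped = intro.fdm_single_window(p[:, [1, 0, 2, 3]])
            if np.isnan(f):
                assert np.isnan(f_swapped)
                continue
            assert abs(f) <= 1.0 + 1e-12
            assert f == pytest.approx(-f_swapped, abs=1e-12)

    def test_windowed_values_match_single_window_recomputation(self):
        """Cumulative-sum path equals direct per-window evaluation."""
        from introscape import windows as win

        model = sim.SpeciesTreeModel(
            newick="(((P1:1.0,P2:1.0):1.0,P3:2.0):1.0,O:3.0);",
            samples_per_taxon={"P1": 2, "P2": 2, "P3": 2, "O": 2},
        )
        m, _ = sim.simulate_dataset(
            model, 40, sim.MutationModel(20), sim.ScaffoldLayout(), seed=13
        )
        pm = model.population_map()
        ws = win.snp_windows(m, 100, 50)
        table = intro.fdm_windows(m, pm, TRIO, ws)
        p, _ = intro.population_frequencies(m, pm, TRIO)
        var_idx = win.variant_site_indices(m)
        for w, f in zip(ws, table["fdm"]):
            direct = intro.fdm_single_window(p[var_idx[w.snp_start : w.snp_end]])
            assert f == pytest.approx(direct, abs=1e-12)


class TestTrios:
    def test_cherry_orientation_on_guide_tree(self):
        tree = dendropy.Tree.get(data="(((A,B),C),O);", schema="newick")
        trios = intro.enumerate_trios(tree, "O")
        assert trios == [("A", "B", "C", False)]

    def test_four_ingroup_taxa_give_four_trios(self):
        tree = dendropy.Tree.get(data="((((A,B),C),D),O);", schema="newick")
        trios = intro.enumerate_trios(tree, "O")
        assert len(trios) == 4
        assert ("A", "B", "C", False) in trios
        assert ("A", "B", "D", False) in trios
        # C is closer to (A,B) than D: P3=D for the (A,C)/(B,C) trios
        assert ("A", "C", "D", False) in trios

    def test_polytomy_falls_back_to_lexicographic(self):
        tree = dendropy.Tree.get(data="((A,B,C),O);", schema="newick")
        trios = intro.enumerate_trios(tree, "O")
        assert trios == [("A", "B", "C", True)]

    def test_missing_population_rejected(self):
        tree = dendropy.Tree.get(data="(((A,B),C),O);", schema="newick")
        with pytest.raises(ValidationError):
            intro.enumerate_trios(tree, "O", populations=["A", "B", "X"])


class TestFBranch:
    @pytest.fixture(scope="class")
    @staticmethod
    def pulse_data():
        model = sim.SpeciesTreeModel(
            newick="(((A:1.0,B:1.0):1.0,C:2.0):1.0,O:3.0);",
            samples_per_taxon={"A": 3, "B": 3, "C": 3, "O": 3},
            migration=[
                sim.MigrationPulse(donor="C", recipient="B", time=0.25, fraction=0.15)
            ],
        )
        m, _ = sim.simulate_dataset(
            model, 250, sim.MutationModel(25), sim.ScaffoldLayout(), seed=99
        )
        guide = dendropy.Tree.get(data="(((A,B),C),O);", schema="newick")
        return model, m, guide

    def test_terminal_branch_single_sister_reduces_to_f4(self, pulse_data):
        model, m, guide = pulse_data
        pm = model.population_map()
        fb = intro.f_branch(guide, m, pm, "O", n_blocks=10)
        row_b = fb.branches.index(frozenset({"B"}))
        col_c = fb.tips.index("C")
        f4 = intro.f4_ratio(m, pm, ("A", "B", "C", "O"))
        assert fb.values[row_b, col_c] == pytest.approx(max(f4, 0.0))

    def test_invalid_cells_where_c_in_branch_or_sister(self, pulse_data):
        model, m, guide = pulse_data
        fb = intro.f_branch(guide, m, model.population_map(), "O", n_blocks=10)
        row_b = fb.branches.index(frozenset({"B"}))
        assert np.isnan(fb.values[row_b, fb.tips.index("A")])
        assert np.isnan(fb.values[row_b, fb.tips.index("B")])

    def test_signal_localized_to_recipient_branch(self, pulse_data):
        model, m, guide = pulse_data
        fb = intro.f_branch(guide, m, model.population_map(), "O", n_blocks=10)
        row_b = fb.branches.index(frozenset({"B"}))
        row_a = fb.branches.index(frozenset({"A"}))
        col_c = fb.tips.index("C")
        assert fb.values[row_b, col_c] > 0.05
        assert fb.values[row_a, col_c] < fb.values[row_b, col_c]
        assert fb.significant[row_b, col_c]


class TestRegionElevation:
    def _table(self, values, starts=None):
        import pandas as pd

        starts = starts or [i * 100 for i in range(len(values))]
        return pd.DataFrame(
            {
                "scaffold": "s1",
                "start": starts,
                "end": [s + 100 for s in starts],
                "fdm": values,
            }
        )

    def test_flat_region_gives_t_zero_p_half(self):
        table = self._table([0.2] * 10)
        diff, t, p = intro.region_elevation_test(table, "s1", (0, 300))
        assert diff == pytest.approx(0.0, abs=1e-12)
        assert t == 0.0 and p == 0.5

    def test_elevated_region_small_p(self):
        values = [0.0] * 8 + [0.5, 0.51]
        table = self._table(values)
        diff, t, p = intro.region_elevation_test(table, "s1", (800, 1_000))
        assert diff > 0 and p < 0.05

    def test_t_matches_textbook_one_sample_formula(self):
        region = [0.30, 0.25, 0.35, 0.28, 0.32]
        rest = [0.10, 0.12, 0.08, 0.11, 0.09]
        table = self._table(region + rest)
        diff, t, p = intro.region_elevation_test(table, "s1", (0, 500))
        mu = np.mean(region + rest)
        x = np.array(region)
        t_hand = (x.mean() - mu) / (x.std(ddof=1) / np.sqrt(len(x)))
        assert t == pytest.approx(t_hand)
        assert diff == pytest.approx(x.mean() - mu)

    def test_too_few_region_windows_rejected(self):
        table = self._table([0.1] * 5)
        with pytest.raises(ValidationError):
            intro.region_elevation_test(table, "s1", (0, 100))
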