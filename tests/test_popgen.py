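"""Parsimony scoring/search, bootstrap consensus, and multilocus LD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cghindel.popgen import (
    PresenceAbsenceMatrix,
    bootstrap_consensus,
    camin_sokal_score,
    ia_s,
    ia_s_permutation_test,
    search_most_parsimonious,
    wagner_score,
)
from cghindel.trees import Tree

from oracles import (
    all_unrooted_topologies,
    brute_force_camin_sokal,
    brute_force_wagner,
    ia_s_reference,
)


def mat(rows, strains, loci=None):
    rows = np.atleast_2d(rows)
    loci = loci or [f"l{j}" for j in range(rows.shape[1])]
    return PresenceAbsenceMatrix.from_arrays(rows, strains, loci)


def carriers_mat(carrier_sets, strains):
    cols = [[1 if s in c else 0 for c in carrier_sets] for s in strains]
    return mat(np.array(cols), strains)


class TestScores:
    t_ab = Tree.from_newick("((A,B),(C,D));")
    t_ac = Tree.from_newick("((A,C),(B,D));")
    strains = list("ABCD")

    def test_all_zero_like_matrix_rejected(self):
        with pytest.raises(ValueError, match="no carriers"):
            mat(np.zeros((4, 1), dtype=int), self.strains)

    def test_wagner_counts_match_examples(self):
        m = carriers_mat([{"A", "B"}], self.strains)
        assert wagner_score(self.t_ab, m) == 1
        assert wagner_score(self.t_ac, m) == 2
        m3 = carriers_mat([{"A", "B", "C"}], self.strains)
        assert wagner_score(self.t_ab, m3) == 1  # root 1, one loss at D

    def test_camin_sokal_counts_match_examples(self):
        m1 = carriers_mat([{"B"}], self.strains)
        assert camin_sokal_score(self.t_ab, m1) == 1
        assert camin_sokal_score(self.t_ac, m1) == 1
        m2 = carriers_mat([{"A", "B"}], self.strains)
        assert camin_sokal_score(self.t_ac, m2) == 2  # independent origins
        m3 = carriers_mat([{"A", "B", "C"}], self.strains)
        assert camin_sokal_score(self.t_ab, m3) == 2
        assert wagner_score(self.t_ab, m3) == 1  # the methods diverge here

    def test_scores_sum_over_loci(self):
        m = carriers_mat([{"A", "B"}, {"B"}, {"A", "B", "C"}], self.strains)
        assert wagner_score(self.t_ab, m) == 1 + 1 + 1
        assert camin_sokal_score(self.t_ab, m) == 1 + 1 + 2

    def test_leaf_mismatch_rejected(self):
        m = carriers_mat([{"A"}], list("ABCE"))
        with pytest.raises(ValueError, match="leaves"):
            wagner_score(self.t_ab, m)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**62 - 1))
    def test_brute_force_equivalence_and_ordering_n6(self, seed):
        rng = np.random.default_rng(seed)
        strains = list("ABCDEF")
        carriers = set()
        while not 0 < len(carriers) < 6:
            carriers = {s for s in strains if rng.random() < 0.5}
        m = carriers_mat([carriers], strains)
        topologies = list(all_unrooted_topologies(strains))
        tree = topologies[int(rng.integers(len(topologies)))]
        w = wagner_score(tree, m)
        cs = camin_sokal_score(tree, m)
        assert w == brute_force_wagner(tree, carriers)
        assert cs == brute_force_camin_sokal(tree, carriers)
        assert cs >= w


class TestSearch:
    def _clade_matrix(self):
        # markers are clades of a caterpillar genealogy whose first-
        # diverging lineage is strain A, so no marker contains A and every
        # internal branch of the unrooted tree is marked
        strains = list("ABCDEF")
        clades = [{"E", "F"}, {"D", "E", "F"}, {"C", "D", "E", "F"},
                  {"A"}, {"B"}, {"C"}, {"D"}, {"E"}, {"F"}]
        return carriers_mat(clades * 3, strains), Tree.from_newick("(A,(B,(C,(D,(E,F)))));")

    @pytest.mark.parametrize("method", ["wagner", "camin_sokal"])
    @pytest.mark.parametrize("strategy", ["exhaustive", "branch_and_bound", "heuristic"])
    def test_compatible_characters_unique_optimum(self, method, strategy):
        m, truth = self._clade_matrix()
        trees = search_most_parsimonious(m, method, strategy, seed=3)
        assert len(trees) == 1
        assert trees[0].same_unrooted_topology(truth)

    def test_branch_and_bound_equals_exhaustive_on_random(self):
        rng = np.random.default_rng(9)
        strains = list("ABCDEF")
        for _ in range(5):
            vals = (rng.random((6, 12)) < 0.4).astype(int)
            vals[:, vals.sum(axis=0) == 0] = 1  # no empty columns
            m = mat(vals, strains)
            for method in ("wagner", "camin_sokal"):
                ex = search_most_parsimonious(m, method, "exhaustive")
                bb = search_most_parsimonious(m, method, "branch_and_bound")
                assert ex[0].score == bb[0].score
                assert {frozenset(t.bipartitions()) for t in ex} == {
                    frozenset(t.bipartitions()) for t in bb
                }

    def test_single_informative_character_ties(self):
        strains = list("ABCDE")
        m = carriers_mat([{"A", "B"}], strains)
        trees = search_most_parsimonious(m, "wagner", "exhaustive")
        split = frozenset({"B"})  # side excluding A of the A|B cherry... n/a
        # every optimal tree shows the {A,B} bipartition
        ab = frozenset({"C", "D", "E"})
        assert all(ab in t.bipartitions() for t in trees)
        # number of unrooted topologies over 5 taxa displaying a given
        # cherry: 3 of 15
        assert len(trees) == 3

    def test_exhaustive_rejected_beyond_eight(self):
        strains = [f"s{i}" for i in range(9)]
        m = carriers_mat([{"s0"}], strains)
        with pytest.raises(ValueError, match="at most 8"):
            search_most_parsimonious(m, "wagner", "exhaustive")


class TestBootstrap:
    def test_degenerate_bootstrap_full_support(self):
        strains = list("ABCDE")
        m = carriers_mat([{"A", "B"}] * 10, strains)
        res = bootstrap_consensus(m, "wagner", n_replicates=20, seed=1)
        key = frozenset({"C", "D", "E"})
        assert res.support[key] == pytest.approx(100.0)
        assert key in res.consensus.bipartitions()

    def test_clonal_recovery_with_support(self):
        strains = [f"S{i}" for i in range(8)]
        spec = strains[-1]
        for s in reversed(strains[:-1]):
            spec = f"({s},{spec})"
        truth = Tree.from_newick(spec + ";")
        clades = [frozenset([s]) for s in strains]
        for k in range(2, 7):
            clades.append(frozenset(strains[-k:]))
        m = carriers_mat([set(c) for c in clades for _ in range(12)], strains)
        for method in ("camin_sokal", "wagner"):
            res = bootstrap_consensus(m, method, n_replicates=50, seed=5, n_jumbles=5)
            assert res.consensus.same_unrooted_topology(truth)
            assert min(res.support[s] for s in truth.bipartitions()) >= 95.0

    def test_group_frequency_and_reproducibility(self):
        strains = list("ABCDE")
        m = carriers_mat([{"A", "B"}] * 5 + [{"D", "E"}] * 5, strains)
        r1 = bootstrap_consensus(m, "wagner", n_replicates=30, seed=7)
        r2 = bootstrap_consensus(m, "wagner", n_replicates=30, seed=7)
        assert r1.consensus.to_newick() == r2.consensus.to_newick()
        assert r1.support == r2.support
        assert r1.group_frequency(["A", "B"]) > 90.0
        assert r1.group_frequency(["A", "C"]) < 20.0


class TestIaS:
    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(2)
        vals = (rng.random((8, 30)) < 0.4).astype(int)
        keep = (vals.sum(axis=0) > 0) & (vals.sum(axis=0) < 8)
        vals = vals[:, keep]
        m = mat(vals, [f"s{i}" for i in range(8)])
        assert ia_s(m).ia_s == pytest.approx(ia_s_reference(vals), abs=1e-12)

    def test_duplicated_column_closed_form(self):
        col = np.zeros((12, 1), int)
        col[0, 0] = 1
        l = 100
        m = mat(np.repeat(col, l, axis=1), [f"s{i}" for i in range(12)])
        theta = 2 * 1 * 11 / (12 * 11)
        expected = (l * (1 - theta) - 1) / (l - 1)
        assert ia_s(m).ia_s == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_strain_and_locus_order(self):
        rng = np.random.default_rng(6)
        vals = (rng.random((10, 25)) < 0.5).astype(int)
        keep = (vals.sum(axis=0) > 0) & (vals.sum(axis=0) < 10)
        vals = vals[:, keep]
        strains = [f"s{i}" for i in range(10)]
        base = ia_s(mat(vals, strains)).ia_s
        perm_s = rng.permutation(10)
        perm_l = rng.permutation(vals.shape[1])
        shuffled = ia_s(mat(vals[perm_s][:, perm_l], [strains[i] for i in perm_s])).ia_s
        assert shuffled == pytest.approx(base, abs=1e-12)

    def test_constant_column_rejected(self):
        vals = np.ones((5, 3), dtype=int)
        m = PresenceAbsenceMatrix.from_arrays(vals, list("ABCDE"), ["a", "b", "c"])
        with pytest.raises(ValueError, match="constant"):
            ia_s(m)

    def test_equilibrium_mean_near_zero(self):
        rng = np.random.default_rng(10)
        values = []
        for _ in range(30):
            v = (rng.random((12, 150)) < rng.uniform(0.2, 0.8, 150)).astype(int)
            cs = v.sum(axis=0)
            v = v[:, (cs > 0) & (cs < 12)]
            values.append(ia_s(mat(v, [f"s{i}" for i in range(12)])).ia_s)
        assert abs(np.mean(values)) < 0.01

    def test_permutation_test_detects_linkage(self):
        col = (np.arange(12) < 6).astype(int).reshape(-1, 1)
        m = mat(np.repeat(col, 40, axis=1), [f"s{i}" for i in range(12)])
        res = ia_s_permutation_test(m, n_permutations=199, seed=3)
        assert res.p_value <= 0.01
        assert res.n_permutations == 199

    def test_permutation_null_preserves_frequencies(self):
        rng = np.random.default_rng(4)
        v = (rng.random((10, 20)) < 0.3).astype(int)
        cs = v.sum(axis=0)
        v = v[:, (cs > 0) & (cs < 10)]
        m = mat(v, [f"s{i}" for i in range(10)])
        res = ia_s_permutation_test(m, n_permutations=50, seed=1)
        assert res.null_values.shape == (50,)
        assert 0 < res.p_value <= 1
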