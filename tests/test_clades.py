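"""Root-clade selection and RC proportion profiles."""

import dendropy
import numpy as np
import pytest

from rhosurvey.clades import (
    family_proportions,
    filter_metagenomes,
    profile_metagenome,
    select_root_clades,
)
from rhosurvey.errors import ValidationError
from rhosurvey.formats import PlacementTable, ReadSupportTable, ReferenceTree
from rhosurvey.simulate import simulate_placements, simulate_tree

from _oracles import best_cut_by_enumeration


def _placement_table(tree, frag_to_leaf, lengths):
    leaf_edge = {next(iter(tree.leafset(e))): e
                 for e in tree.edge_leafsets() if len(tree.leafset(e)) == 1}
    rows = {f: (leaf_edge[leaf], 1.0) for f, leaf in frag_to_leaf.items()}
    return PlacementTable("mg", rows=rows, fragment_lengths=lengths,
                          edge_leafsets=tree.edge_leafsets())


class TestSelectRootClades:
    def test_balanced_tree_symmetry(self, small_tree):
        rcs = select_root_clades(small_tree, n_rc=4)
        assert sorted(sorted(c) for c in rcs.clades.values()) == [
            ["A", "B"], ["C", "D"], ["E", "F"], ["G", "H"]]

    def test_caterpillar_root_children(self):
        newick = "((((A:1,B:1):1,C:1):1,D:1):1,E:1);"
        tree = ReferenceTree(dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True))
        rcs = select_root_clades(tree, n_rc=2)
        assert sorted(sorted(c) for c in rcs.clades.values()) == [
            ["A", "B", "C", "D"], ["E"]]

    def test_n_rc_above_leaf_count_errors(self, small_tree):
        with pytest.raises(ValidationError, match="max"):
            select_root_clades(small_tree, n_rc=9)

    def test_clades_partition_the_leaves(self, small_tree):
        rcs = select_root_clades(small_tree, n_rc=3)
        all_leaves = [l for c in rcs.clades.values() for l in c]
        assert sorted(all_leaves) == sorted(small_tree.leaf_labels)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_enumeration(self, seed):
        """DP cut equals full enumeration of covering cuts on random trees."""
        rng = np.random.default_rng(seed)
        tree = simulate_tree(int(rng.integers(16, 40)), seed=seed)
        n_rc = int(rng.integers(2, 9))
        rcs = select_root_clades(tree, n_rc=n_rc)
        assert frozenset(rcs.cut_edges.values()) == \
            best_cut_by_enumeration(tree, n_rc)


class TestProfileMetagenome:
    def test_all_fragments_one_clade(self, small_tree):
        rcs = select_root_clades(small_tree, n_rc=4)
        pt = _placement_table(small_tree, {"f1": "A", "f2": "B"},
                              {"f1": 100, "f2": 50})
        reads = ReadSupportTable(reads={"f1": 10, "f2": 5})
        prof = profile_metagenome(pt, reads, rcs)
        rc_ab = rcs.assign(frozenset({"A"}))
        assert prof.p[rc_ab] == pytest.approx(1.0)
        assert sum(prof.p.values()) == pytest.approx(1.0)

    def test_read_length_weighting(self, small_tree):
        """h/l weights: (10,100) and (20,200) carry equal weight."""
        rcs = select_root_clades(small_tree, n_rc=4)
        pt = _placement_table(small_tree, {"f1": "A", "f2": "C"},
                              {"f1": 100, "f2": 200})
        reads = ReadSupportTable(reads={"f1": 10, "f2": 20})
        prof = profile_metagenome(pt, reads, rcs)
        assert prof.p[rcs.assign(frozenset({"A"}))] == pytest.approx(0.5)
        assert prof.p[rcs.assign(frozenset({"C"}))] == pytest.approx(0.5)

    def test_zero_read_fragment_contributes_nothing(self, small_tree):
        rcs = select_root_clades(small_tree, n_rc=4)
        pt = _placement_table(small_tree, {"f1": "A", "f2": "E"},
                              {"f1": 100, "f2": 100})
        with_zero = profile_metagenome(
            pt, ReadSupportTable(reads={"f1": 7, "f2": 0}), rcs)
        without = profile_metagenome(
            _placement_table(small_tree, {"f1": "A"}, {"f1": 100}),
            ReadSupportTable(reads={"f1": 7}), rcs)
        assert with_zero.p == without.p
        assert with_zero.n_fragments == 2  # still located in the tree

    def test_above_cut_placement_dropped(self, small_tree):
        rcs = select_root_clades(small_tree, n_rc=4)
        # place on an internal edge spanning two RCs (A,B,C,D)
        abcd_edge = next(e for e, ls in small_tree.edge_leafsets().items()
                         if ls == frozenset({"A", "B", "C", "D"}))
        pt = PlacementTable("mg", rows={"f1": (abcd_edge, 1.0)},
                            fragment_lengths={"f1": 80},
                            edge_leafsets=small_tree.edge_leafsets())
        prof = profile_metagenome(pt, ReadSupportTable(reads={"f1": 4}), rcs)
        assert prof.n_unassigned == 1
        assert prof.is_empty

    def test_empty_profile_marker_not_nan(self, small_tree):
        rcs = select_root_clades(small_tree, n_rc=4)
        pt = _placement_table(small_tree, {}, {})
        prof = profile_metagenome(pt, ReadSupportTable(), rcs)
        assert prof.is_empty
        assert not any(np.isnan(v) for v in prof.p.values())

    def test_order_invariance(self, small_tree):
        rcs = select_root_clades(small_tree, n_rc=4)
        frags = {"f1": "A", "f2": "C", "f3": "E", "f4": "G"}
        lengths = {f: 50 + 10 * i for i, f in enumerate(frags)}
        reads = ReadSupportTable(reads={f: 3 + i for i, f in enumerate(frags)})
        a = profile_metagenome(_placement_table(small_tree, frags, lengths),
                               reads, rcs)
        rev = dict(reversed(list(frags.items())))
        b = profile_metagenome(_placement_table(small_tree, rev, lengths),
                               reads, rcs)
        assert a.p == b.p

    def test_weight_additivity_under_fragment_split(self, small_tree):
        """Splitting a fragment's reads into two same-RC, same-length
        fragments leaves the profile unchanged."""
        rcs = select_root_clades(small_tree, n_rc=4)
        whole = profile_metagenome(
            _placement_table(small_tree, {"f": "A", "g": "C"},
                             {"f": 100, "g": 100}),
            ReadSupportTable(reads={"f": 10, "g": 5}), rcs)
        split = profile_metagenome(
            _placement_table(small_tree, {"f1": "A", "f2": "B", "g": "C"},
                             {"f1": 100, "f2": 100, "g": 100}),
            ReadSupportTable(reads={"f1": 4, "f2": 6, "g": 5}), rcs)
        for rc in rcs.rc_ids:
            assert split.p[rc] == pytest.approx(whole.p[rc])


class TestFilterMetagenomes:
    def test_strict_threshold_reading(self, small_tree):
        rcs = select_root_clades(small_tree, n_rc=4)
        profs = []
        for n in (9, 10, 11):
            pt = _placement_table(small_tree, {f"f{i}": "A" for i in range(n)},
                                  {f"f{i}": 100 for i in range(n)})
            reads = ReadSupportTable(reads={f"f{i}": 1 for i in range(n)})
            profs.append(profile_metagenome(pt, reads, rcs))
        kept = filter_metagenomes(profs, min_fragments=10)
        assert [p.n_fragments for p in kept] == [10, 11]

    def test_empty_and_identity(self):
        assert filter_metagenomes([], 10) == []


class TestFamilyProportions:
    def test_single_family_clade(self, small_tree):
        rcs = select_root_clades(small_tree, n_rc=4)
        rc_ab = rcs.assign(frozenset({"A"}))
        prof_p = {rc: 0.0 for rc in rcs.rc_ids}
        prof_p[rc_ab] = 1.0
        from rhosurvey.clades import RCProfile
        fams = family_proportions(RCProfile("m", prof_p, 5), rcs, small_tree)
        assert fams["xanthorhodopsin"] == pytest.approx(1.0)

    def test_weighted_sum_hand_computed(self, small_tree):
        """RC{C,D} is 50% halo/50% proteo at p=0.4; RC{E,F} is 100% halo at
        p=0.6 → halo 0.8, proteo 0.2."""
        rcs = select_root_clades(small_tree, n_rc=4)
        from rhosurvey.clades import RCProfile
        p = {rc: 0.0 for rc in rcs.rc_ids}
        p[rcs.assign(frozenset({"C"}))] = 0.4
        p[rcs.assign(frozenset({"E"}))] = 0.6
        fams = family_proportions(RCProfile("m", p, 5), rcs, small_tree)
        assert fams["halorhodopsin"] == pytest.approx(0.8)
        assert fams["proteorhodopsin"] == pytest.approx(0.2)

    def test_unknown_mass_conserved(self, small_tree):
        rcs = select_root_clades(small_tree, n_rc=4)
        from rhosurvey.clades import RCProfile
        p = {rc: 0.25 for rc in rcs.rc_ids}
        fams = family_proportions(RCProfile("m", p, 5), rcs, small_tree)
        assert "unknown" in fams
        assert sum(fams.values()) == pytest.approx(1.0)


class TestSimulatedPlacementRecovery:
    def test_profile_recovered_within_multinomial_error(self):
        tree = simulate_tree(48, seed=11)
        rcs = select_root_clades(tree, n_rc=8)
        rng = np.random.default_rng(5)
        target = dict(zip(rcs.rc_ids, rng.dirichlet(np.ones(8))))
        pt, reads = simulate_placements(tree, rcs, target, n_reads=100_000,
                                        seed=21)
        prof = profile_metagenome(pt, reads, rcs)
        err = max(abs(prof.p[rc] - target[rc]) for rc in rcs.rc_ids)
        assert sum(prof.p.values()) == pytest.approx(1.0, abs=1e-9)
        assert err < 0.01
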