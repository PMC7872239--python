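"""RC elimination, grid consensus vote, and recursive grouping."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from rhosurvey.clustering import (
    EliminationConfig,
    GridConfig,
    NoMajorityError,
    cluster_grid,
    eliminate_rcs,
    recursive_grouping,
)
from rhosurvey.errors import DegenerateMatrixError, ValidationError
from rhosurvey.simulate import (
    ProfileSimSpec,
    simulate_hierarchical_profiles,
    simulate_profiles,
)


def _blobs(seed=0, n_per=10, centers=((1.0, 1.0), (6.0, 6.0)), spread=0.1):
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for g, c in enumerate(centers):
        rows.append(rng.normal(c, spread, size=(n_per, len(c))))
        labels += [g] * n_per
    X = np.vstack(rows)
    df = pd.DataFrame(X, index=[f"m{i}" for i in range(len(X))],
                      columns=[f"RC{j}" for j in range(X.shape[1])])
    return df, np.array(labels)


class TestEliminateRCs:
    def test_all_zero_column_removed_as_constant(self):
        df = pd.DataFrame({"RC1": [0.1, 0.2, 0.3], "RC2": [0.0, 0.0, 0.0]})
        reduced, report = eliminate_rcs(df)
        assert list(reduced.columns) == ["RC1"]
        assert report[0].rc_id == "RC2" and report[0].criterion == "constant"

    def test_sparse_criterion_hand_built(self):
        """96 of 100 metagenomes below 0.001, the rest below 0.02."""
        col = np.full(100, 0.0005)
        col[:4] = 0.01
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"RC1": rng.uniform(0.1, 0.9, 100), "RC2": col})
        reduced, report = eliminate_rcs(df)
        assert list(reduced.columns) == ["RC1"]
        assert (report[0].rc_id, report[0].criterion) == ("RC2", "sparse")

    def test_sparse_not_triggered_when_major_values_large(self):
        col = np.full(100, 0.0005)
        col[:4] = 0.05  # above sparse_major_prop
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"RC1": rng.uniform(0.1, 0.9, 100), "RC2": col})
        reduced, _ = eliminate_rcs(df)
        assert "RC2" in reduced.columns

    def test_perfectly_correlated_column_removed_keeping_first(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0.1, 0.9, 30)
        df = pd.DataFrame({"RC1": a, "RC2": 2 * a, "RC3": rng.uniform(0, 1, 30)})
        reduced, report = eliminate_rcs(df)
        assert list(reduced.columns) == ["RC1", "RC3"]
        assert (report[0].rc_id, report[0].criterion) == ("RC2", "correlated")

    def test_anticorrelation_counts_as_fully_correlated(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0.1, 0.9, 30)
        df = pd.DataFrame({"RC1": a, "RC2": 1 - a, "RC3": rng.uniform(0, 1, 30)})
        reduced, report = eliminate_rcs(df)
        assert "RC2" not in reduced.columns

    def test_each_criterion_triggered_exactly_once(self):
        """One fixture per criterion; each removes exactly its column."""
        rng = np.random.default_rng(5)
        n = 100
        base = rng.uniform(0.1, 0.9, n)
        sparse = np.full(n, 0.0005)
        sparse[:3] = 0.015
        df = pd.DataFrame({
            "RC1": base,
            "RC2": sparse,                  # (i)
            "RC3": np.full(n, 0.25),        # (ii)
            "RC4": 0.5 * base,              # (iii) with RC1
            "RC5": rng.uniform(0.1, 0.9, n),
        })
        reduced, report = eliminate_rcs(df)
        assert list(reduced.columns) == ["RC1", "RC5"]
        assert {(r.rc_id, r.criterion) for r in report} == {
            ("RC2", "sparse"), ("RC3", "constant"), ("RC4", "correlated")}

    def test_idempotence(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.dirichlet(np.ones(8), size=40),
                          columns=[f"RC{j}" for j in range(8)])
        df["RC7"] = 0.0
        once, _ = eliminate_rcs(df)
        twice, report2 = eliminate_rcs(once)
        pd.testing.assert_frame_equal(once, twice)
        assert report2 == []

    def test_all_columns_removed_is_an_error(self):
        df = pd.DataFrame({"RC1": [0.1, 0.1, 0.1], "RC2": [0.2, 0.2, 0.2]})
        with pytest.raises(ValidationError, match="threshold"):
            eliminate_rcs(df)

    def test_threshold_validation(self):
        with pytest.raises(ValidationError):
            EliminationConfig(sparse_major_frac=1.5)


class TestClusterGrid:
    def test_two_blobs_recovered_with_k2(self):
        df, truth = _blobs(seed=0)
        res = cluster_grid(df, seed=0)
        assert res.k == 2
        assert adjusted_rand_score(truth, res.labels) == 1.0
        # every combination's k-vote went to 2 on this geometry
        assert set(res.voted_k.values()) == {2}

    def test_identical_rows_degenerate(self):
        df = pd.DataFrame(np.ones((5, 3)), columns=list("abc"))
        with pytest.raises(DegenerateMatrixError):
            cluster_grid(df, seed=0)

    def test_too_few_rows(self):
        df = pd.DataFrame(np.eye(2), columns=["a", "b"])
        with pytest.raises(ValidationError):
            cluster_grid(df, seed=0)

    def test_permutation_invariance(self):
        df, truth = _blobs(seed=2, n_per=8)
        res = cluster_grid(df, seed=0)
        perm = np.random.default_rng(0).permutation(len(df))
        dfp = df.iloc[perm]
        resp = cluster_grid(dfp, seed=0)
        lab = {m: l for m, l in zip(res.members, res.labels)}
        labp = {m: l for m, l in zip(resp.members, resp.labels)}
        a = [lab[m] for m in df.index]
        b = [labp[m] for m in df.index]
        assert adjusted_rand_score(a, b) == 1.0

    def test_restricted_grid_still_votes(self):
        df, truth = _blobs(seed=3)
        grid = GridConfig(distances=("manhattan",), methods=("average",),
                          k_max=5)
        res = cluster_grid(df, grid, seed=0)
        assert (res.distance, res.method) == ("manhattan", "average")
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_vote_tallies_recorded(self):
        df, _ = _blobs(seed=4)
        res = cluster_grid(df, seed=0)
        assert res.k_votes  # every combination has its index→k votes
        assert all(isinstance(v, dict) for v in res.k_votes.values())
        assert set(res.combo_votes) <= set(GridConfig().combo_indices)


class TestRecursiveGrouping:
    def test_planted_flat_groups_recovered(self):
        spec = ProfileSimSpec(n_groups=3, n_per_group=13, n_rc=15,
                              dirichlet_concentration=0.5,
                              noise_scale=0.015, min_separation=0.3, seed=9)
        df, truth = simulate_profiles(spec)
        root = recursive_grouping(df, min_group=10, seed=1)
        top = root.top_partition()
        labels = [top[m] for m in df.index]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_small_input_single_group(self):
        df, _ = _blobs(seed=5, n_per=4)  # 8 rows < min_group
        root = recursive_grouping(df, min_group=10, seed=0)
        assert root.is_leaf
        assert root.note == "below-min-size"

    def test_zero_noise_hierarchy_leaves_match_subgroups(self):
        df, sup, sub = simulate_hierarchical_profiles(
            dirichlet_concentration=0.5, super_separation=0.4,
            sub_scale=0.08, noise_scale=0.0, seed=3)
        root = recursive_grouping(df, min_group=10, seed=0)
        leaf = root.leaf_partition()
        leaf_labels = [leaf[m] for m in df.index]
        assert adjusted_rand_score(sub, leaf_labels) == 1.0
        # every recovered leaf nests inside one planted super-group
        sup_of = dict(zip(df.index, sup))
        for node in root.leaves():
            assert len({sup_of[m] for m in node.members}) == 1

    def test_degenerate_branch_isolated(self):
        """One duplicated-row group degenerates; the sibling still resolves."""
        rng = np.random.default_rng(11)
        dup = np.tile(rng.dirichlet(np.ones(6)), (12, 1))
        other = rng.dirichlet(np.ones(6) * 30, size=12) + 0.5
        other /= other.sum(axis=1, keepdims=True)
        X = np.vstack([dup, other])
        df = pd.DataFrame(X, index=[f"m{i}" for i in range(24)],
                          columns=[f"RC{j}" for j in range(6)])
        root = recursive_grouping(df, min_group=10, seed=0)
        assert not root.is_leaf
        dup_leaf = next(n for n in root.leaves() if "m0" in n.members)
        assert set(dup_leaf.members) == {f"m{i}" for i in range(12)}
        # the degenerate branch carries a note instead of raising
        assert dup_leaf.note and dup_leaf.grid_result is None

    def test_termination_by_shrinking_groups(self):
        df, _ = _blobs(seed=12, n_per=15, spread=0.5,
                       centers=((0, 0), (4, 4)))
        root = recursive_grouping(df, min_group=10, seed=0)
        for leaf in root.leaves():
            assert leaf.is_leaf
        # recursion bottomed out: every leaf is small or noted
        assert all(len(l.members) < 10 or l.note for l in root.leaves())
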