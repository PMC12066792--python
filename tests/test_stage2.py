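"""Variance-reduction splitting, tree growth, leaf merging, group assignment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from drgmix.stage2 import (
    DecisionTreeGrouper,
    GroupingScheme,
    TreeNode,
    TreeParams,
    grow_tree,
    merge_small_leaves,
    run_trials,
    variance_reduction,
)


class TestVarianceReduction:
    def test_perfect_split(self):
        assert variance_reduction([1, 1, 5, 5], [[1, 1], [5, 5]]) == pytest.approx(1.0)

    def test_constant_costs_convention(self):
        assert variance_reduction([3, 3, 3, 3], [[3, 3], [3, 3]]) == 0.0

    def test_hand_arithmetic_population_variance(self):
        # Var({1,2,3,4}) = 1.25; halves have Var 0.25 each, weighted sum
        # 0.5*0.25 + 0.5*0.25 = 0.25 -> (1.25 - 0.25)/1.25 = 0.8
        assert variance_reduction([1, 2, 3, 4], [[1, 2], [3, 4]]) == pytest.approx(0.8)

    @pytest.mark.parametrize("parts", [[[1, 2], []], [[1], [2]], [[1, 2, 3, 4, 5]]])
    def test_bad_partition_rejected(self, parts):
        with pytest.raises(ValueError):
            variance_reduction([1, 2, 3, 4], parts)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            costs = rng.normal(size=20)
            cut = rng.integers(1, 19)
            riv = variance_reduction(costs, [costs[:cut], costs[cut:]])
            assert -1e-12 <= riv <= 1.0 + 1e-12


def _frame(levels_by_factor, cost):
    df = pd.DataFrame(levels_by_factor)
    return df, np.asarray(cost, dtype=float)


class TestGrowTree:
    def test_binary_factor_with_separated_means(self):
        df, cost = _frame({"f": ["a", "a", "b", "b"] * 5}, [100, 100, 1000, 1000] * 5)
        root = grow_tree(df, cost, TreeParams(factors=("f",), min_leaf=1))
        assert root.split_factor == "f"
        assert sorted(c.mean for c in root.children.values()) == [100.0, 1000.0]

    def test_zero_variance_gives_single_leaf(self):
        df, cost = _frame({"f": list("abab")}, [5, 5, 5, 5])
        root = grow_tree(df, cost, TreeParams(factors=("f",), min_leaf=1))
        assert root.is_leaf

    def test_no_factors_is_error(self):
        df, cost = _frame({"f": ["a"]}, [1.0])
        with pytest.raises(ValueError):
            grow_tree(df, cost, TreeParams(factors=(), min_leaf=1))

    def test_root_split_matches_exhaustive_search(self):
        # on tiny cohorts the chosen root factor must equal brute force
        rng = np.random.default_rng(13)
        for trial in range(20):
            n = int(rng.integers(6, 13))
            df = pd.DataFrame(
                {
                    "u": rng.choice(list("ab"), n),
                    "v": rng.choice(list("xyz"), n),
                    "w": rng.choice(list("pq"), n),
                }
            )
            cost = rng.normal(1000, 300, n)
            factors = ("u", "v", "w")
            gains = {}
            for f in factors:
                levels = pd.unique(df[f])
                if len(levels) < 2:
                    continue
                gains[f] = variance_reduction(cost, [cost[(df[f] == l).to_numpy()] for l in levels])
            root = grow_tree(df, cost, TreeParams(factors=factors, min_leaf=1, max_depth=1))
            if not gains or max(gains.values()) < 0.001:
                assert root.is_leaf
            else:
                best = max(gains.values())
                first_best = next(f for f in factors if f in gains and gains[f] >= best - 1e-12)
                assert root.split_factor == first_best

    def test_agrees_with_sklearn_on_binary_factor(self):
        # one binary factor: our multiway split == sklearn's depth-1 regression tree
        from sklearn.tree import DecisionTreeRegressor

        rng = np.random.default_rng(5)
        x = rng.integers(0, 2, 200)
        cost = 500.0 + 400.0 * x + rng.normal(0, 50, 200)
        df = pd.DataFrame({"f": np.where(x == 1, "high", "low")})
        root = grow_tree(df, cost, TreeParams(factors=("f",), min_leaf=1))
        sk = DecisionTreeRegressor(max_depth=1).fit(x.reshape(-1, 1), cost)
        ours = sorted(c.mean for c in root.children.values())
        theirs = sorted(sk.tree_.value.squeeze()[1:])
        assert ours == pytest.approx(theirs)

    def test_factor_used_once_per_path(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"a": rng.choice(list("xy"), 60), "b": rng.choice(list("uv"), 60)})
        cost = rng.normal(0, 1, 60) + 10 * (df["a"] == "x") + 5 * (df["b"] == "u")
        root = grow_tree(df, cost.to_numpy(), TreeParams(factors=("a", "b"), min_leaf=1))

        def paths(node, seen):
            if node.is_leaf:
                return
            assert node.split_factor not in seen
            for child in node.children.values():
                paths(child, seen | {node.split_factor})

        paths(root, set())


def _leaf(leaf_id, n, mean):
    return TreeNode(n=n, mean=mean, variance=0.0, leaf_id=leaf_id)


def _tree_with_leaves(leaves):
    root = TreeNode(n=sum(l.n for l in leaves), mean=0.0, variance=1.0, split_factor="f")
    root.children = {str(i): leaf for i, leaf in enumerate(leaves)}
    return root


class TestMergeSmallLeaves:
    def test_nearest_mean_absorption(self):
        root = _tree_with_leaves([_leaf(0, 150, 90.0), _leaf(1, 300, 100.0), _leaf(2, 400, 500.0)])
        scheme = merge_small_leaves(root, min_leaf=200, factors=("f",))
        assert scheme.n_groups == 2
        assert scheme.merge_map[0] == scheme.merge_map[1] != scheme.merge_map[2]
        # renumbered ascending by mean: merged low-cost group is 1
        assert scheme.merge_map[0] == 1
        merged_mean = (150 * 90.0 + 300 * 100.0) / 450
        assert scheme.group_means[1] == pytest.approx(merged_mean)

    def test_identity_when_all_large(self):
        root = _tree_with_leaves([_leaf(0, 300, 50.0), _leaf(1, 250, 10.0)])
        scheme = merge_small_leaves(root, min_leaf=200, factors=("f",))
        assert scheme.n_groups == 2
        assert scheme.merge_map == {1: 1, 0: 2}  # ascending mean order

    def test_floor_case_single_group(self):
        root = _tree_with_leaves([_leaf(0, 10, 1.0), _leaf(1, 20, 2.0), _leaf(2, 5, 9.0)])
        scheme = merge_small_leaves(root, min_leaf=200, factors=("f",))
        assert scheme.n_groups == 1
        assert set(scheme.merge_map.values()) == {1}

    def test_k_never_increases_and_min_leaf_met(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            leaves = [
                _leaf(i, int(rng.integers(1, 400)), float(rng.uniform(0, 1000)))
                for i in range(int(rng.integers(1, 8)))
            ]
            root = _tree_with_leaves(leaves)
            scheme = merge_small_leaves(root, min_leaf=150, factors=("f",))
            assert scheme.n_groups <= len(leaves)
            if scheme.n_groups > 1:
                assert all(n >= 150 for n in scheme.group_sizes.values())
            ordered = [scheme.group_means[g] for g in sorted(scheme.group_means)]
            assert ordered == sorted(ordered)


class TestAssignment:
    @pytest.fixture()
    def fitted(self, cohort_frame):
        grouper = DecisionTreeGrouper(min_leaf=200, random_state=0).fit(
            cohort_frame, cohort_frame["cost"].to_numpy()
        )
        return grouper

    def test_training_cohort_partition(self, fitted, cohort_frame):
        groups = fitted.predict(cohort_frame)
        assert len(groups) == len(cohort_frame)
        counts = pd.Series(groups).value_counts()
        assert counts.sum() == len(cohort_frame)
        assert set(counts.index) == set(range(1, fitted.n_groups_ + 1))
        if fitted.n_groups_ > 1:
            assert counts.min() >= 200

    def test_unseen_level_routes_to_nearest_mean_child(self):
        df, cost = _frame({"f": ["a"] * 10 + ["b"] * 10}, [100.0] * 10 + [1000.0] * 10)
        root = grow_tree(df, cost, TreeParams(factors=("f",), min_leaf=1))
        scheme = merge_small_leaves(root, min_leaf=1, factors=("f",))
        unseen = pd.Series({"f": "zzz"})
        # parent mean 550: child means 100 and 1000 are equidistant; the
        # lower-mean child wins the tie
        assert scheme.assign(unseen) == scheme.assign(pd.Series({"f": "a"}))

    def test_scheme_json_round_trip(self, fitted, cohort_frame):
        text = fitted.scheme_.to_json()
        loaded = GroupingScheme.from_json(text)
        assert loaded.to_json() == text
        sample = cohort_frame.head(50)
        assert (loaded.assign_frame(sample) == fitted.predict(sample)).all()


class TestTrialsAndDeterminism:
    def test_identical_seed_identical_scheme_bytes(self, cohort_frame):
        cost = cohort_frame["cost"].to_numpy()
        a = DecisionTreeGrouper(random_state=3).fit(cohort_frame, cost).scheme_.to_json()
        b = DecisionTreeGrouper(random_state=3).fit(cohort_frame, cost).scheme_.to_json()
        assert a == b

    def test_single_trial(self, cohort_frame):
        trials, consistent, final = run_trials(
            cohort_frame, cohort_frame["cost"].to_numpy(), TreeParams(n_trials=1, seed=1)
        )
        assert len(trials) == 1 and consistent
        assert final.n_groups >= 1

    def test_trials_consistent_on_strong_signal(self, cohort_frame):
        trials, consistent, final = run_trials(
            cohort_frame,
            cohort_frame["cost"].to_numpy(),
            TreeParams(factors=("patient_type", "hospital_level"), min_leaf=50, n_trials=5, seed=2),
        )
        assert consistent
        assert {t.root_factor for t in trials} == {final.root.split_factor}
        for t in trials:
            assert 0.0 <= t.test_riv_pct <= 100.0
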