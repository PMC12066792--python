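"""Stage 2: multiway decision-tree grouping by cost-variance reduction.

An ID3-style tree on purely categorical grouping factors (patient type,
hospital level, age stratum, ...) with a continuous target, hospitalization
cost.  Classic ID3 splits on information gain, which has no continuous-
target form; here each node splits on the unused factor whose multiway
split maximizes the reduction-in-variance fraction

    RIV = (Var_parent - sum_k (n_k / n) Var_k) / Var_parent

with Var the population variance.  Leaves smaller than ``min_leaf`` are
merged into the group with nearest mean cost, smallest leaf first, until
every group reaches ``min_leaf`` (or one group remains); final groups are
renumbered 1..K by ascending mean cost.  Assignment is total: a record
showing a factor level unseen in training routes to the child whose
training mean is nearest its parent's mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "TreeParams",
    "TreeNode",
    "GroupingScheme",
    "TrialResult",
    "variance_reduction",
    "grow_tree",
    "merge_small_leaves",
    "assign_group",
    "run_trials",
    "DecisionTreeGrouper",
]

DEFAULT_FACTORS = ("patient_type", "hospital_level", "age_bin", "insurance", "los_bin")


def variance_reduction(parent: Sequence[float], parts: Sequence[Sequence[float]]) -> float:
    """Fraction of the parent's population variance removed by a partition.

    Zero by convention when the parent variance is zero.  Raises if the
    partition has an empty block or does not cover the parent.
    """
    parent = np.asarray(parent, dtype=float)
    if parent.size == 0:
        raise ValueError("parent must be non-empty")
    sizes = [len(p) for p in parts]
    if any(s == 0 for s in sizes):
        raise ValueError("partition blocks must be non-empty")
    if sum(sizes) != parent.size:
        raise ValueError("partition must be exhaustive and disjoint")
    var_parent = float(np.var(parent))
    if var_parent == 0.0:
        return 0.0
    n = parent.size
    weighted = sum(len(p) / n * float(np.var(np.asarray(p, dtype=float))) for p in parts)
    return (var_parent - weighted) / var_parent


@dataclass
class TreeParams:
    """Growth and trial settings for the grouping tree."""

    factors: tuple[str, ...] = DEFAULT_FACTORS
    min_leaf: int = 200
    min_gain: float = 0.001
    max_depth: int | None = None
    train_fraction: float = 0.7
    n_trials: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")


@dataclass
class TreeNode:
    """One node: split factor and children if internal, leaf id if leaf."""

    n: int
    mean: float
    variance: float
    split_factor: str | None = None
    children: dict[str, "TreeNode"] = field(default_factory=dict)
    leaf_id: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.split_factor is None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for level in sorted(self.children):
            out.extend(self.children[level].leaves())
        return out

    def to_dict(self) -> dict:
        d: dict = {"n": self.n, "mean": round(self.mean, 6), "variance": round(self.variance, 6)}
        if self.is_leaf:
            d["leaf_id"] = self.leaf_id
        else:
            d["split_factor"] = self.split_factor
            d["children"] = {lvl: c.to_dict() for lvl, c in sorted(self.children.items())}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(n=d["n"], mean=d["mean"], variance=d["variance"])
        if "split_factor" in d:
            node.split_factor = d["split_factor"]
            node.children = {lvl: cls.from_dict(c) for lvl, c in d["children"].items()}
        else:
            node.leaf_id = d["leaf_id"]
        return node


def _grow(
    df: pd.DataFrame,
    cost: np.ndarray,
    factors: list[str],
    params: TreeParams,
    depth: int,
    counter: list[int],
) -> TreeNode:
    node = TreeNode(n=len(cost), mean=float(np.mean(cost)), variance=float(np.var(cost)))
    stop = (
        node.variance == 0.0
        or node.n < 2 * params.min_leaf
        or (params.max_depth is not None and depth >= params.max_depth)
        or not factors
    )
    best_factor, best_gain = None, -1.0
    if not stop:
        for factor in factors:  # declared order breaks gain ties
            levels = df[factor].to_numpy()
            uniq = pd.unique(levels)
            if len(uniq) < 2:
                continue
            parts = [cost[levels == u] for u in uniq]
            gain = variance_reduction(cost, parts)
            if gain > best_gain + 1e-15:
                best_factor, best_gain = factor, gain
        if best_factor is None or best_gain < params.min_gain:
            stop = True
    if stop:
        node.leaf_id = counter[0]
        counter[0] += 1
        return node
    node.split_factor = best_factor
    remaining = [f for f in factors if f != best_factor]
    levels = df[best_factor].to_numpy()
    for level in sorted(str(u) for u in pd.unique(levels)):
        mask = levels == level
        node.children[level] = _grow(
            df.loc[mask], cost[mask], remaining, params, depth + 1, counter
        )
    return node


def grow_tree(df: pd.DataFrame, cost: Sequence[float], params: TreeParams) -> TreeNode:
    """Grow the multiway variance-reduction tree; deterministic.

    Each factor is used at most once per root-to-leaf path.  A node becomes
    a leaf when it has zero variance, fewer than ``2 * min_leaf`` records,
    maximal depth, or no factor achieving ``min_gain``.
    """
    if not params.factors:
        raise ValueError("no grouping factors supplied")
    missing = [f for f in params.factors if f not in df.columns]
    if missing:
        raise ValueError(f"factors not in data: {missing}")
    cost = np.asarray(cost, dtype=float)
    if len(cost) != len(df):
        raise ValueError("cost length must match data length")
    if len(cost) == 0:
        raise ValueError("cannot grow a tree on an empty cohort")
    return _grow(df.reset_index(drop=True), cost, list(params.factors), params, 0, [0])


@dataclass
class GroupingScheme:
    """Fitted tree plus the small-leaf merge map; assigns final groups 1..K."""

    root: TreeNode
    merge_map: dict[int, int]
    group_means: dict[int, float]
    group_sizes: dict[int, int]
    factors: tuple[str, ...]

    @property
    def n_groups(self) -> int:
        return len(self.group_means)

    def _leaf_for(self, row) -> TreeNode:
        node = self.root
        while not node.is_leaf:
            level = str(row[node.split_factor])
            child = node.children.get(level)
            if child is None:
                # unseen level: the child whose mean is nearest the parent's
                child = min(
                    node.children.values(),
                    key=lambda c: (abs(c.mean - node.mean), c.mean),
                )
            node = child
        return node

    def assign(self, row) -> int:
        """Final group id for one record (a mapping or Series of factors)."""
        return self.merge_map[self._leaf_for(row).leaf_id]

    def assign_frame(self, df: pd.DataFrame) -> np.ndarray:
        return np.asarray([self.assign(row) for _, row in df.iterrows()], dtype=int)

    def to_json(self) -> str:
        payload = {
            "factors": list(self.factors),
            "tree": self.root.to_dict(),
            "merge_map": {str(k): v for k, v in sorted(self.merge_map.items())},
            "group_means": {str(k): round(v, 6) for k, v in sorted(self.group_means.items())},
            "group_sizes": {str(k): v for k, v in sorted(self.group_sizes.items())},
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroupingScheme":
        d = json.loads(text)
        return cls(
            root=TreeNode.from_dict(d["tree"]),
            merge_map={int(k): v for k, v in d["merge_map"].items()},
            group_means={int(k): v for k, v in d["group_means"].items()},
            group_sizes={int(k): v for k, v in d["group_sizes"].items()},
            factors=tuple(d["factors"]),
        )


def merge_small_leaves(root: TreeNode, min_leaf: int, factors: Sequence[str]) -> GroupingScheme:
    """Absorb undersized leaves into the nearest-mean group, smallest first.

    Groups start as the tree's leaves; while any group is below ``min_leaf``
    and more than one group remains, the smallest such group (ties: lowest
    leaf id) merges into the surviving group with nearest mean cost (ties:
    lower mean).  Final groups are renumbered 1..K by ascending mean.
    """
    leaves = root.leaves()
    # group id -> (member leaf ids, n, mean)
    groups: dict[int, dict] = {
        lf.leaf_id: {"leaves": [lf.leaf_id], "n": lf.n, "mean": lf.mean} for lf in leaves
    }
    while len(groups) > 1:
        small = [(g["n"], min(g["leaves"]), gid) for gid, g in groups.items() if g["n"] < min_leaf]
        if not small:
            break
        _, _, gid = min(small)
        g = groups.pop(gid)
        target = min(
            groups,
            key=lambda other: (abs(groups[other]["mean"] - g["mean"]), groups[other]["mean"]),
        )
        t = groups[target]
        total = t["n"] + g["n"]
        t["mean"] = (t["mean"] * t["n"] + g["mean"] * g["n"]) / total
        t["n"] = total
        t["leaves"] = sorted(t["leaves"] + g["leaves"])
    ordered = sorted(groups.values(), key=lambda g: (g["mean"], min(g["leaves"])))
    merge_map: dict[int, int] = {}
    group_means: dict[int, float] = {}
    group_sizes: dict[int, int] = {}
    for new_id, g in enumerate(ordered, start=1):
        for leaf_id in g["leaves"]:
            merge_map[leaf_id] = new_id
        group_means[new_id] = g["mean"]
        group_sizes[new_id] = g["n"]
    return GroupingScheme(
        root=root,
        merge_map=merge_map,
        group_means=group_means,
        group_sizes=group_sizes,
        factors=tuple(factors),
    )


def assign_group(row, scheme: GroupingScheme) -> int:
    """Final group id for one record; total over all factor levels."""
    return scheme.assign(row)


@dataclass
class TrialResult:
    """One train/test trial: the fitted scheme and its test-set footprint."""

    scheme: GroupingScheme
    n_groups: int
    root_factor: str | None
    test_riv_pct: float
    test_n: int


def run_trials(df: pd.DataFrame, cost: Sequence[float], params: TreeParams):
    """Repeated random train/test trials plus a full-cohort refit.

    Returns ``(trials, consistent, final_scheme)``: per-trial schemes and
    test-set variance reduction, a flag saying whether every trial produced
    the same group count and root split factor, and a scheme refitted on
    the full cohort (the published-style result).
    """
    from .evaluation import scheme_riv

    cost = np.asarray(cost, dtype=float)
    rng = np.random.default_rng(params.seed)
    n = len(df)
    trials: list[TrialResult] = []
    for _ in range(params.n_trials):
        perm = rng.permutation(n)
        n_train = int(round(params.train_fraction * n))
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        root = grow_tree(df.iloc[train_idx], cost[train_idx], params)
        scheme = merge_small_leaves(root, params.min_leaf, params.factors)
        test_groups = scheme.assign_frame(df.iloc[test_idx])
        parts = [cost[test_idx][test_groups == g] for g in np.unique(test_groups)]
        riv = scheme_riv([p for p in parts if len(p)], cost[test_idx]) if len(test_idx) else 0.0
        trials.append(
            TrialResult(
                scheme=scheme,
                n_groups=scheme.n_groups,
                root_factor=scheme.root.split_factor,
                test_riv_pct=riv,
                test_n=len(test_idx),
            )
        )
    consistent = (
        len({t.n_groups for t in trials}) <= 1 and len({t.root_factor for t in trials}) <= 1
    )
    final_root = grow_tree(df, cost, params)
    final_scheme = merge_small_leaves(final_root, params.min_leaf, params.factors)
    return trials, consistent, final_scheme


class DecisionTreeGrouper(BaseEstimator):
    """Variance-reduction tree grouper with the sklearn fit/predict idiom.

    fit(X, y) grows the multiway tree on the categorical factor columns of
    ``X`` against cost ``y`` and merges undersized leaves; predict(X)
    returns final group ids 1..K for any records with those factor columns.

    Attributes
    ----------
    scheme_ : the fitted :class:`GroupingScheme`.
    n_groups_ : number of final groups K.
    trials_, trials_consistent_ : set when ``n_trials > 0``; repeated
        train/test trials and whether they agreed on K and the root factor.
    """

    def __init__(
        self,
        factors: tuple[str, ...] = DEFAULT_FACTORS,
        min_leaf: int = 200,
        min_gain: float = 0.001,
        max_depth: int | None = None,
        train_fraction: float = 0.7,
        n_trials: int = 0,
        random_state: int = 0,
    ):
        self.factors = factors
        self.min_leaf = min_leaf
        self.min_gain = min_gain
        self.max_depth = max_depth
        self.train_fraction = train_fraction
        self.n_trials = n_trials
        self.random_state = random_state

    def _params(self) -> TreeParams:
        return TreeParams(
            factors=tuple(self.factors),
            min_leaf=self.min_leaf,
            min_gain=self.min_gain,
            max_depth=self.max_depth,
            train_fraction=self.train_fraction,
            n_trials=self.n_trials,
            seed=self.random_state,
        )

    def fit(self, X: pd.DataFrame, y: Sequence[float]) -> "DecisionTreeGrouper":
        params = self._params()
        if self.n_trials > 0:
            self.trials_, self.trials_consistent_, self.scheme_ = run_trials(X, y, params)
        else:
            root = grow_tree(X, np.asarray(y, dtype=float), params)
            self.scheme_ = merge_small_leaves(root, params.min_leaf, params.factors)
        self.n_groups_ = self.scheme_.n_groups
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "scheme_")
        return self.scheme_.assign_frame(X)
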