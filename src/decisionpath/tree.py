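"""Population decision-tree comparator.

A single tree is fitted to the whole training set by top-down recursive
multiway splitting on information gain (the "deviance" criterion), then
pruned bottom-up, and its leaf probabilities are BDeu-smoothed exactly as
the decision-path models' are — so the comparison with the personalized
learners isolates the modelling strategy, not the estimator.

This is a standard greedy multiway information-gain tree, not a port of
any particular CART implementation: splits are multiway on a variable's
full (discretized) domain rather than binary, and pruning is a Bayesian
bottom-up collapse (children's summed Dirichlet-multinomial log marginal
vs. the merged node's) rather than cost-complexity.  Training rows that
lack the split variable follow the child that received the most training
rows, and the same child handles missing values at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DiscreteDataset, PersonInstance, ScoringConfig, MISSING
from .scoring import bdeu_theta, entropy_bits, _dirichlet_marginal

__all__ = ["TreeNode", "TreeControls", "fit_population_tree", "tree_predict",
           "tree_path_for_person"]


@dataclass
class TreeNode:
    """Internal node (split variable + child per domain value) or leaf."""

    counts: np.ndarray                      # class counts of rows reaching the node
    theta: np.ndarray                       # BDeu-smoothed leaf distribution
    variable: str | None = None             # None => leaf
    children: dict = field(default_factory=dict)   # value -> TreeNode
    missing_value: object = None            # branch taken for a missing value

    @property
    def is_leaf(self) -> bool:
        return self.variable is None

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return sum(c.n_leaves() for c in self.children.values())

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(c.depth() for c in self.children.values())


@dataclass(frozen=True)
class TreeControls:
    min_leaf: int = 1
    max_depth: int | None = None
    prune: bool = True


def _multiway_gain(y_sub: np.ndarray, assigned: np.ndarray, n_values: int,
                   k: int, counts_D: np.ndarray):
    """IG of a full-domain split; rows are pre-assigned to value branches."""
    table = np.zeros((n_values, k), dtype=np.int64)
    np.add.at(table, (assigned, y_sub), 1)
    sizes = table.sum(axis=1)
    n = y_sub.shape[0]
    child_h = sum(sizes[v] / n * entropy_bits(table[v]) for v in range(n_values) if sizes[v])
    return entropy_bits(counts_D) - child_h, table, sizes


def _assign_branches(col: np.ndarray, n_values: int):
    """Map each row to a branch value; missing rows join the largest branch."""
    present = col >= 0
    sizes = np.bincount(col[present], minlength=n_values)
    majority = int(np.argmax(sizes))  # ties -> earliest domain value
    assigned = np.where(present, col, majority)
    return assigned, majority


def _grow(train: DiscreteDataset, idx: np.ndarray, used: set, depth: int,
          config: ScoringConfig, controls: TreeControls) -> TreeNode:
    k = train.n_classes
    y_sub = train.y[idx]
    counts = np.bincount(y_sub, minlength=k).astype(np.int64)
    node = TreeNode(counts=counts, theta=bdeu_theta(counts, config))
    if (
        idx.size < 2
        or (y_sub == y_sub[0]).all()
        or (controls.max_depth is not None and depth >= controls.max_depth)
    ):
        return node
    best = None  # (gain, j, assigned, majority)
    for j in range(len(train.schema)):
        if j in used:
            continue
        n_values = len(train.schema[j].domain)
        assigned, majority = _assign_branches(train.X[idx, j], n_values)
        gain, _, sizes = _multiway_gain(y_sub, assigned, n_values, k, counts)
        nonempty = sizes[sizes > 0]
        if nonempty.size < 2 or nonempty.min() < controls.min_leaf:
            continue
        if best is None or gain > best[0]:
            best = (gain, j, assigned, majority)
    if best is None:
        return node
    _, j, assigned, majority = best
    spec = train.schema[j]
    node.variable = spec.name
    node.missing_value = spec.domain[majority]
    for v, value in enumerate(spec.domain):
        child_idx = idx[assigned == v]
        node.children[value] = _grow(train, child_idx, used | {j}, depth + 1,
                                     config, controls)
    return node


def _prune(node: TreeNode, config: ScoringConfig, k: int) -> TreeNode:
    """Bottom-up collapse when the split does not earn its keep.

    An internal node whose children are all leaves is collapsed to a leaf
    unless the children's summed Dirichlet-multinomial log marginal
    exceeds the merged node's (alpha per class = 1/K on both sides).
    """
    if node.is_leaf:
        return node
    node.children = {v: _prune(c, config, k) for v, c in node.children.items()}
    if all(c.is_leaf for c in node.children.values()):
        a = config.alpha_jk(k)
        split_ll = sum(
            _dirichlet_marginal(c.counts, a)
            for c in node.children.values()
            if c.counts.sum() > 0
        )
        merged_ll = _dirichlet_marginal(node.counts, a)
        if split_ll <= merged_ll:
            node.variable = None
            node.children = {}
            node.missing_value = None
    return node


def fit_population_tree(
    train: DiscreteDataset,
    config: ScoringConfig = ScoringConfig(),
    controls: TreeControls = TreeControls(),
) -> TreeNode:
    """Fit (and optionally prune) the population tree on the full dataset."""
    if train.n_rows == 0:
        raise ValueError("empty training set")
    root = _grow(train, np.arange(train.n_rows), set(), 0, config, controls)
    if controls.prune:
        root = _prune(root, config, train.n_classes)
    return root


def _route(tree: TreeNode, train_like_codes: np.ndarray, index_of: dict):
    """Walk from the root to a leaf; yields (node, branch value taken)."""
    node = tree
    path = []
    while not node.is_leaf:
        j = index_of[node.variable]
        code = train_like_codes[j] if j is not None else MISSING
        if code == MISSING:
            value = node.missing_value
        else:
            # domain order == code order by construction
            value = list(node.children.keys())[code]
        path.append((node.variable, value))
        node = node.children[value]
    return node, path


def _person_router(person: PersonInstance):
    index_of = {v.name: j for j, v in enumerate(person.schema)}
    return person.codes, index_of


def tree_predict(tree: TreeNode, person: PersonInstance) -> float:
    """Route the person to one leaf; return its smoothed theta_p.

    The positive value is taken to be the last target-domain value unless
    the caller tracks it; use :func:`tree_predict_index` for control.
    """
    leaf, _ = _route(tree, *_person_router(person))
    return float(leaf.theta[-1])


def tree_predict_index(tree: TreeNode, person: PersonInstance, positive_index: int) -> float:
    leaf, _ = _route(tree, *_person_router(person))
    return float(leaf.theta[positive_index])


def tree_path_for_person(tree: TreeNode, person: PersonInstance) -> list:
    """Ordered conjuncts along the person's routing path (root to leaf)."""
    _, path = _route(tree, *_person_router(person))
    return path
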