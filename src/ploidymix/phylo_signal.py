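"""Fritz's D: phylogenetic signal of a binary trait on a rooted tree.

The observed statistic ``d`` sums, over all internal nodes of a bifurcating
tree, the absolute difference between the trait estimates of the node's two
children, where internal estimates come from branch-length-weighted pruning
averages of the tip states (contrasts-style, tips to root).  ``d`` is scaled
between the means of two simulated nulls,

    D = (d_obs - mean(d_brownian)) / (mean(d_random) - mean(d_brownian)),

so that D ~ 1 for a trait shuffled randomly over tips and D ~ 0 for a trait
generated by thresholding a Brownian liability.  Significance is read from
both null ensembles: ``p_random`` is the probability of a trait as-or-more
phylogenetically clumped than observed under random shuffling (d_null <=
d_obs), ``p_brownian`` the probability of as-or-less clumping than observed
under Brownian evolution (d_null >= d_obs).  Both use the (r+1)/(n+1)
finite-sample correction.

Null replicates are evaluated in bulk: the pruning pass is expressed with
per-node weights precomputed from branch lengths, so thousands of replicate
trait vectors prune in a single vectorised sweep.
"""

from __future__ import annotations

import logging
import random as _random
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "DStatResult",
    "read_newick",
    "tree_from_dendropy",
    "sister_diff_sum",
    "d_statistic",
]

logger = logging.getLogger(__name__)

#: Offset added to zero-length branches (polytomy resolution, coalescent-unit
#: trees) so pruning weights stay finite.
ZERO_BRANCH_OFFSET = 1e-8


@dataclass
class PhyloTree:
    """A rooted, strictly bifurcating tree flattened to index arrays.

    Nodes 0..n_tips-1 are tips (order of ``tip_labels``); internal nodes
    follow in postorder, the root last.  ``children[k]`` holds the two child
    indices of internal node ``n_tips + k``; ``edge_len[v]`` is the length of
    the edge above node ``v`` (0 for the root).
    """

    tip_labels: list[str]
    children: np.ndarray  # (n_internal, 2) int
    edge_len: np.ndarray  # (n_nodes,) float
    parent: np.ndarray  # (n_nodes,) int; root's parent = -1

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.edge_len)

    def to_newick(self) -> str:
        """Serialise back to a rooted Newick string."""

        def emit(v: int) -> str:
            if v < self.n_tips:
                return f"{self.tip_labels[v]}:{self.edge_len[v]:.10g}"
            i, j = self.children[v - self.n_tips]
            inner = f"({emit(i)},{emit(j)})"
            if self.parent[v] == -1:
                return inner
            return f"{inner}:{self.edge_len[v]:.10g}"

        return emit(self.n_nodes - 1) + ";"

    def pruning_weights(
        self, use_branch_lengths: bool = True
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-internal-node child weights for the pruning average.

        For internal node k with children (i, j) of effective lengths
        (e_i, e_j): value(k) = w_i * value(i) + w_j * value(j) with
        w_i = e_j / (e_i + e_j), and k's own effective length grows by the
        parallel sum e_i*e_j/(e_i+e_j).
        """
        bl = self.edge_len if use_branch_lengths else np.ones(self.n_nodes)
        bl = np.maximum(bl, ZERO_BRANCH_OFFSET)
        eff = bl.copy()
        n_int = len(self.children)
        weights = np.empty((n_int, 2))
        for k in range(n_int):
            i, j = self.children[k]
            ei, ej = eff[i], eff[j]
            weights[k, 0] = ej / (ei + ej)
            weights[k, 1] = ei / (ei + ej)
            eff[self.n_tips + k] += ei * ej / (ei + ej)
        return weights, eff


def tree_from_dendropy(
    tree: dendropy.Tree, seed: int = 0, default_branch_length: float = 1.0
) -> PhyloTree:
    """Flatten a dendropy tree, resolving polytomies and filling in missing
    branch lengths (deterministically given ``seed``)."""
    tree = tree.clone(depth=1)
    tree.suppress_unifurcations()
    if any(len(nd.child_nodes()) > 2 for nd in tree.preorder_node_iter()):
        logger.warning("resolving polytomies with zero-length branches")
        tree.resolve_polytomies(rng=_random.Random(seed))

    labels = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else leaf.label
        if label is None:
            raise ValueError("tree has an unlabeled tip")
        labels.append(label)
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")

    tip_index = {}
    post_nodes = list(tree.postorder_node_iter())
    index: dict[int, int] = {}
    n_tips = len(labels)
    next_internal = n_tips
    tip_labels: list[str] = [""] * n_tips
    next_tip = 0
    for nd in post_nodes:
        if nd.is_leaf():
            index[id(nd)] = next_tip
            tip_labels[next_tip] = nd.taxon.label if nd.taxon else nd.label
            next_tip += 1
        else:
            index[id(nd)] = next_internal
            next_internal += 1
    del tip_index

    n_nodes = next_internal
    children = np.empty((n_nodes - n_tips, 2), dtype=np.int64)
    edge_len = np.zeros(n_nodes)
    parent = np.full(n_nodes, -1, dtype=np.int64)
    warned_missing = False
    for nd in post_nodes:
        v = index[id(nd)]
        if nd.parent_node is not None:
            parent[v] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                warned_missing = True
                edge_len[v] = default_branch_length
            else:
                edge_len[v] = float(nd.edge.length)
        if not nd.is_leaf():
            kids = nd.child_nodes()
            if len(kids) != 2:
                raise ValueError("tree is not strictly bifurcating after resolution")
            children[v - n_tips] = [index[id(kids[0])], index[id(kids[1])]]
    if warned_missing:
        logger.warning(
            "missing branch lengths replaced by %g", default_branch_length
        )
    return PhyloTree(
        tip_labels=tip_labels, children=children, edge_len=edge_len, parent=parent
    )


def read_newick(path: str | Path, seed: int = 0) -> PhyloTree:
    """Read a rooted Newick tree; polytomies are resolved to bifurcations
    with zero-length branches (seeded), missing branch lengths become 1."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises reader-specific types
        if "Duplicate taxon" in str(exc) or "duplicate" in str(exc).lower():
            raise ValueError(f"duplicate tip labels in {path}") from exc
        raise ValueError(f"unparseable Newick in {path}: {exc}") from exc
    return tree_from_dendropy(tree, seed=seed)


def _states_array(tree: PhyloTree, trait: Mapping[str, int]) -> np.ndarray:
    missing = [l for l in tree.tip_labels if l not in trait]
    extra = [l for l in trait if l not in set(tree.tip_labels)]
    if missing or extra:
        raise ValueError(
            f"trait must cover every tip exactly once (missing={missing[:5]}, "
            f"extra={extra[:5]})"
        )
    x = np.array([trait[l] for l in tree.tip_labels], dtype=float)
    if not set(np.unique(x)) <= {0.0, 1.0}:
        raise ValueError("trait states must be 0/1")
    return x


def _d_values(
    tree: PhyloTree, tip_values: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Sister-clade difference sums for each column of ``tip_values``.

    ``tip_values`` has shape (n_tips, R); returns shape (R,).
    """
    r = tip_values.shape[1]
    values = np.empty((tree.n_nodes, r))
    values[: tree.n_tips] = tip_values
    d = np.zeros(r)
    n_tips = tree.n_tips
    for k, (i, j) in enumerate(tree.children):
        vi, vj = values[i], values[j]
        d += np.abs(vi - vj)
        values[n_tips + k] = weights[k, 0] * vi + weights[k, 1] * vj
    return d


def sister_diff_sum(
    tree: PhyloTree, trait: Mapping[str, int], use_branch_lengths: bool = True
) -> float:
    """Observed d: sum over internal nodes of |estimate(left) - estimate(right)|.

    Internal estimates are branch-length-weighted pruning averages of tip
    states.  Raises for a monomorphic trait (d is then trivially 0 and D is
    undefined).
    """
    x = _states_array(tree, trait)
    if x.min() == x.max():
        raise ValueError("D undefined: trait is monomorphic on the tips")
    weights, _ = tree.pruning_weights(use_branch_lengths)
    return float(_d_values(tree, x[:, None], weights)[0])


def brownian_liabilities(
    tree: PhyloTree,
    n_rep: int,
    rng: np.random.Generator,
    use_branch_lengths: bool = True,
) -> np.ndarray:
    """Tip liabilities of ``n_rep`` unit-rate Brownian simulations, shape
    (n_tips, n_rep)."""
    bl = tree.edge_len if use_branch_lengths else np.ones(tree.n_nodes)
    bl = np.maximum(bl, ZERO_BRANCH_OFFSET)
    eps = rng.standard_normal((tree.n_nodes, n_rep)) * np.sqrt(bl)[:, None]
    lia = np.zeros((tree.n_nodes, n_rep))
    # preorder: root (last index) downward; parents always have higher index
    for v in range(tree.n_nodes - 2, -1, -1):
        lia[v] = lia[tree.parent[v]] + eps[v]
    return lia[: tree.n_tips]


def threshold_by_rank(
    liabilities: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Binary states: the k tips with the largest liability per replicate get
    state 1 (ties broken by a seeded random jitter)."""
    jitter = rng.random(liabilities.shape) * 1e-12
    order = np.argsort(-(liabilities + jitter), axis=0)
    states = np.zeros_like(liabilities)
    np.put_along_axis(states, order[:k], 1.0, axis=0)
    return states


@dataclass(frozen=True)
class DStatResult:
    """Fritz's D with its two simulation-based p-values."""

    d_obs: float
    d_random_mean: float
    d_brownian_mean: float
    D: float
    p_random: float
    p_brownian: float
    n_perm: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "d_obs": self.d_obs,
            "d_random_mean": self.d_random_mean,
            "d_brownian_mean": self.d_brownian_mean,
            "D": self.D,
            "p_random": self.p_random,
            "p_brownian": self.p_brownian,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def d_statistic(
    tree: PhyloTree,
    trait: Mapping[str, int],
    n_perm: int = 10000,
    seed: int = 0,
    use_branch_lengths: bool = True,
) -> DStatResult:
    """Fritz's D for a binary trait with permutation and Brownian nulls.

    Random replicates shuffle the observed states over tips (prevalence
    preserved); Brownian replicates threshold a unit-rate Brownian liability
    so that exactly the observed number of tips take state 1.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    x = _states_array(tree, trait)
    k = int(x.sum())
    if k == 0 or k == tree.n_tips:
        raise ValueError("D undefined: trait is monomorphic on the tips")
    weights, _ = tree.pruning_weights(use_branch_lengths)
    d_obs = float(_d_values(tree, x[:, None], weights)[0])

    rng = np.random.default_rng(seed)
    # permutation null: shuffle states across tips
    perm_idx = np.argsort(rng.random((n_perm, tree.n_tips)), axis=1)
    perm_states = x[perm_idx].T  # (n_tips, n_perm)
    d_rand = _d_values(tree, perm_states, weights)
    # Brownian-threshold null
    lia = brownian_liabilities(tree, n_perm, rng, use_branch_lengths)
    bm_states = threshold_by_rank(lia, k, rng)
    d_brown = _d_values(tree, bm_states, weights)

    mean_rand = float(d_rand.mean())
    mean_brown = float(d_brown.mean())
    denom = mean_rand - mean_brown
    if abs(denom) < 1e-12:
        raise ValueError(
            "D undefined: random and Brownian null means coincide "
            f"({mean_rand:.6g})"
        )
    d_scaled = (d_obs - mean_brown) / denom
    p_random = (int(np.count_nonzero(d_rand <= d_obs)) + 1) / (n_perm + 1)
    p_brownian = (int(np.count_nonzero(d_brown >= d_obs)) + 1) / (n_perm + 1)
    return DStatResult(
        d_obs=d_obs,
        d_random_mean=mean_rand,
        d_brownian_mean=mean_brown,
        D=d_scaled,
        p_random=p_random,
        p_brownian=p_brownian,
        n_perm=n_perm,
        seed=seed,
    )
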