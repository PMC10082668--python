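"""Consistency-score phylogenetic distance on target members.

Two samples are compared by how much abundance mass they can "match" on a
shared phylogeny.  At each leaf the matched mass is min(S1, S2) and the
unmatched surplus of the larger sample is kept as a residual.  Moving up
the tree, surpluses of *opposite* samples sitting on different child
lineages may still be matched, but attenuated by the branch lengths
separating them: each child's residual is scaled by max(0, 1 - d) for its
branch length d before matching.  The accumulated matched mass at the root
is the consistency score Con(root); with both input vectors normalized to
sum 1 the distance is simply 1 - Con(root), in [0, 1].

The local (FMS) distance runs this recursion on the weighted target-member
vectors only; the global Meta-Storms baseline is the same recursion with
every feature as a member at weight 1.

A scalar recursion (:func:`tree_consistency`) is kept for clarity and
testing; :func:`pairwise_matrix` uses a vectorized engine that evaluates
all sample pairs per tree node in one pass and is bit-identical to the
scalar path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .flex_extraction import TargetMemberSet, weighted_matrix
from .io_formats import FeatureTable, PhyloTree

__all__ = [
    "ConsistencyState",
    "leaf_consistency",
    "combine_children",
    "tree_consistency",
    "fms_distance",
    "global_distance",
    "pairwise_matrix",
    "pairwise_subset",
]

logger = logging.getLogger(__name__)

#: Residual/consistency values below this are flushed to zero so results do
#: not depend on summation order.
FLUSH_EPS = 1e-12


@dataclass
class ConsistencyState:
    """Matched mass plus the per-sample surpluses still unmatched.

    ``con``: mass matched so far in the subtree.
    ``r1``/``r2``: surplus mass of sample 1 / sample 2; after every combine
    at most one of them is positive.
    """

    con: float
    r1: float
    r2: float

    def __post_init__(self) -> None:
        if min(self.con, self.r1, self.r2) < 0:
            raise ValueError("negative consistency state")


def _flush(x: float) -> float:
    return 0.0 if x < FLUSH_EPS else x


def leaf_consistency(a1: float, a2: float) -> ConsistencyState:
    """Matched mass at a tip: min(a1, a2); surplus goes to the larger side."""
    if a1 < 0 or a2 < 0:
        raise ValueError(f"negative abundance ({a1}, {a2})")
    m = min(a1, a2)
    return ConsistencyState(con=_flush(m), r1=_flush(a1 - m), r2=_flush(a2 - m))


def _combine_pair(
    a: ConsistencyState, d_a: float, b: ConsistencyState, d_b: float
) -> ConsistencyState:
    att_a = max(0.0, 1.0 - d_a)
    att_b = max(0.0, 1.0 - d_b)
    pool1 = a.r1 * att_a + b.r1 * att_b
    pool2 = a.r2 * att_a + b.r2 * att_b
    extra = min(pool1, pool2)
    return ConsistencyState(
        con=_flush(a.con + b.con + extra),
        r1=_flush(pool1 - extra),
        r2=_flush(pool2 - extra),
    )


def combine_children(
    child_states: Sequence[ConsistencyState], branch_lengths: Sequence[float]
) -> ConsistencyState:
    """Combine the children of an internal node.

    Each child's residuals are attenuated by max(0, 1 - d) for its branch
    length d, opposite-sample surpluses are matched, and survivors propagate
    upward.  Multifurcations are resolved pairwise left-to-right through
    zero-length internal edges (equivalent to an arbitrary binary
    resolution).
    """
    if len(child_states) != len(branch_lengths):
        raise ValueError("one branch length per child required")
    if any(d < 0 for d in branch_lengths):
        raise ValueError("negative branch length")
    if not child_states:
        raise ValueError("node without children")
    if len(child_states) == 1:
        # unary node: attenuate and pass through
        att = max(0.0, 1.0 - branch_lengths[0])
        s = child_states[0]
        return ConsistencyState(
            con=s.con, r1=_flush(s.r1 * att), r2=_flush(s.r2 * att)
        )
    acc = child_states[0]
    acc_d = branch_lengths[0]
    for s, d in zip(child_states[1:], branch_lengths[1:]):
        acc = _combine_pair(acc, acc_d, s, d)
        acc_d = 0.0  # accumulated state sits on a zero-length virtual edge
    return acc


def tree_consistency(v1: pd.Series, v2: pd.Series, tree: PhyloTree) -> float:
    """Con(root) for two abundance vectors by post-order recursion.

    Leaves absent from a vector contribute 0; vector entries that are not
    leaves of the tree are a hard error.
    """
    leaves = set(tree.leaf_names)
    for name, vec in (("sample 1", v1), ("sample 2", v2)):
        extra = [f for f in vec.index if f not in leaves and vec[f] > 0]
        if extra:
            raise KeyError(f"{name} members missing from tree: {sorted(extra)}")
    states: dict[int, ConsistencyState] = {}
    for node in tree.tree.postorder(include_self=True):
        if node.is_tip():
            states[id(node)] = leaf_consistency(
                float(v1.get(node.name, 0.0)), float(v2.get(node.name, 0.0))
            )
        else:
            children = node.children
            states[id(node)] = combine_children(
                [states.pop(id(c)) for c in children],
                [c.length for c in children],
            )
    return states[id(tree.tree)].con


def _restricted_normalized(
    table: FeatureTable, target: TargetMemberSet | None
) -> pd.DataFrame:
    """Weighted, T-restricted, per-sample renormalized vectors (members x samples).

    ``target=None`` means the whole community at weight 1 (global mode).
    Samples with zero mass on the members keep all-zero columns (they match
    nothing, giving distance 1 to everything).
    """
    if target is None:
        sub = table.data.copy()
    else:
        sub = weighted_matrix(table, target)
    sub = sub.sort_index()  # canonical row order: renormalization is
    sums = sub.sum(axis=0)  # bit-identical however the members were listed
    zero = sums.index[sums == 0].tolist()
    if zero:
        logger.warning(
            "samples with zero mass on the target members (distance 1 to all): %s",
            zero,
        )
    nz = sums[sums > 0]
    sub.loc[:, nz.index] = sub.loc[:, nz.index] / nz
    return sub


def _check_tree_coverage(
    members: Sequence[str], tree: PhyloTree, table: FeatureTable,
    target: TargetMemberSet | None,
) -> list[str]:
    """Members present in the tree; errors for missing T members, logs drops."""
    leaves = set(tree.leaf_names)
    missing = [m for m in members if m not in leaves]
    if not missing:
        return list(members)
    if target is not None:
        raise KeyError(f"target members missing from tree: {sorted(missing)}")
    dropped_mass = table.data.loc[missing].to_numpy().sum(axis=0)
    logger.warning(
        "%d features absent from tree dropped (max per-sample mass %.4g)",
        len(missing), float(dropped_mass.max()),
    )
    return [m for m in members if m in leaves]


def fms_distance(
    table: FeatureTable,
    sample_1: str,
    sample_2: str,
    target: TargetMemberSet,
    tree: PhyloTree,
) -> float:
    """Local-alignment distance between two samples over the target set.

    The weighted T-restricted vector of each sample is renormalized to sum
    1 and the consistency recursion is run on the shared tree; the distance
    is 1 - Con(root).  If a sample has no mass on T nothing can be matched
    and the distance is 1 (logged).
    """
    if len(target) == 0:
        raise ValueError("empty target member set")
    if sample_1 == sample_2:
        return 0.0
    dm = pairwise_subset(table, [sample_1, sample_2], target, tree)
    return float(dm[0, 1])


def global_distance(
    table: FeatureTable, sample_1: str, sample_2: str, tree: PhyloTree
) -> float:
    """Whole-community Meta-Storms distance (all features, weight 1)."""
    if sample_1 == sample_2:
        return 0.0
    dm = pairwise_subset(table, [sample_1, sample_2], None, tree)
    return float(dm[0, 1])


def pairwise_subset(
    table: FeatureTable,
    sample_ids: Sequence[str],
    target: TargetMemberSet | None,
    tree: PhyloTree,
) -> DistanceMatrix:
    """Distance matrix for a subset of samples (vectorized engine)."""
    sub = _restricted_normalized(table, target)
    members = _check_tree_coverage(list(sub.index), tree, table, target)
    W = sub.loc[members, list(sample_ids)].to_numpy(dtype=float)
    n = len(sample_ids)
    iu = np.triu_indices(n, k=1)
    if iu[0].size == 0:
        return DistanceMatrix(np.zeros((n, n)), ids=list(sample_ids))
    con = _vector_consistency(W, iu[0], iu[1], members, tree)
    mat = np.zeros((n, n))
    mat[iu] = np.clip(1.0 - con, 0.0, 1.0)
    mat = mat + mat.T
    return DistanceMatrix(mat, ids=list(sample_ids))


def pairwise_matrix(
    table: FeatureTable,
    tree: PhyloTree,
    target: TargetMemberSet | None = None,
    threads: int = 1,
) -> DistanceMatrix:
    """All-pairs distance matrix for every sample in the table.

    ``target=None`` computes the global Meta-Storms baseline.  ``threads``
    is accepted for interface compatibility; the engine is a single
    vectorized pass whose output is bit-identical for any value.
    """
    if threads < 1:
        raise ValueError("threads must be >= 1")
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if target is not None and len(target) == 0:
        raise ValueError("empty target member set")
    return pairwise_subset(table, table.sample_ids, target, tree)


def _vector_consistency(
    W: np.ndarray,
    i_idx: np.ndarray,
    j_idx: np.ndarray,
    members: Sequence[str],
    tree: PhyloTree,
) -> np.ndarray:
    """Con(root) for many sample pairs at once.

    ``W`` is members x samples (already weighted and renormalized); the
    recursion state per tree node is a (con, r1, r2) triple of arrays over
    the requested pairs.
    """
    row = {m: k for k, m in enumerate(members)}
    npairs = i_idx.size
    zeros = np.zeros(npairs)
    states: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for node in tree.tree.postorder(include_self=True):
        if node.is_tip():
            k = row.get(node.name)
            if k is None:
                states[id(node)] = (zeros, zeros, zeros)
                continue
            a1 = W[k, i_idx]
            a2 = W[k, j_idx]
            m = np.minimum(a1, a2)
            states[id(node)] = (m, a1 - m, a2 - m)
        else:
            children = node.children
            con, r1, r2 = states.pop(id(children[0]))
            att = max(0.0, 1.0 - children[0].length)
            r1, r2 = r1 * att, r2 * att
            for child in children[1:]:
                c_con, c_r1, c_r2 = states.pop(id(child))
                att = max(0.0, 1.0 - child.length)
                pool1 = r1 + c_r1 * att
                pool2 = r2 + c_r2 * att
                extra = np.minimum(pool1, pool2)
                con = con + c_con + extra
                r1 = pool1 - extra
                r2 = pool2 - extra
            con = np.where(con < FLUSH_EPS, 0.0, con)
            r1 = np.where(r1 < FLUSH_EPS, 0.0, r1)
            r2 = np.where(r2 < FLUSH_EPS, 0.0, r2)
            states[id(node)] = (con, r1, r2)
    return states[id(tree.tree)][0]
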