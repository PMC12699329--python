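"""Maximum-parsimony ancestral reconstruction for binary presence/absence.

Fitch's bottom-up pass yields per-node state sets and the minimal number of
gains plus losses; a deterministic top-down refinement then fixes one
minimum-change labelling in the ACCTRAN spirit (a change is committed at the
first branch on which the preliminary set forces it).  On a binary tree this
labelling never places a same-direction gain (or loss) on both child branches
of one node — the precondition of the simultaneous-evolution contingency
table, whose population size is the number of internal nodes rather than the
number of branches.

State sets are coded as 2-bit masks (bit 0 = absent, bit 1 = present) so
whole profile matrices are reconstructed in a handful of vectorised sweeps.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phylo_io import UNCERTAIN, Tree, TreeArrays, TreeError, align_profile

__all__ = [
    "fitch",
    "fitch_matrix",
    "acctran",
    "acctran_matrix",
    "states_to_events",
    "events_matrix",
    "reconstruct",
]

_BOTH = 0b11


def _leaf_masks(arr: TreeArrays, columns: np.ndarray) -> np.ndarray:
    """(n_nodes x n_cols) mask array with leaf rows filled, internals 0."""
    masks = np.zeros((arr.n_nodes, columns.shape[1]), dtype=np.uint8)
    leaf_rows = np.flatnonzero(arr.is_leaf)
    masks[leaf_rows] = np.uint8(1) << columns.astype(np.uint8)
    return masks


def fitch_matrix(tree: Tree | TreeArrays, columns: np.ndarray):
    """Fitch sets and parsimony scores for many 0/1 leaf columns at once.

    ``columns`` is (n_leaves x n_cols) in tree postorder leaf order.
    Returns ``(masks, scores)``: masks is (n_nodes x n_cols) with 2-bit state
    sets in postorder node order; scores counts union events per column.
    """
    arr = tree.arrays() if isinstance(tree, Tree) else tree
    if not np.isin(columns, (0, 1)).all():
        raise ValueError("leaf states must be 0/1")
    masks = _leaf_masks(arr, columns)
    scores = np.zeros(columns.shape[1], dtype=np.int64)
    for i in np.flatnonzero(~arr.is_leaf):
        kids = arr.children[i]
        if len(kids) != 2:
            raise TreeError("parsimony requires a binary tree; resolve polytomies")
        inter = masks[kids[0]] & masks[kids[1]]
        union = masks[kids[0]] | masks[kids[1]]
        empty = inter == 0
        masks[i] = np.where(empty, union, inter)
        scores += empty
    return masks, scores


def acctran_matrix(
    tree: Tree | TreeArrays,
    masks: np.ndarray,
    root_tie: str = "absent",
) -> np.ndarray:
    """Resolve Fitch sets into one state per node (postorder x cols, int8).

    ``root_tie`` picks the root state when its Fitch set is {0, 1}:
    "absent" assigns 0 (the default, deterministic) and "uncertain" leaves
    the root :data:`UNCERTAIN` so no change is counted on its child branches.
    """
    if root_tie not in ("absent", "uncertain"):
        raise ValueError(f"unknown root_tie {root_tie!r}")
    arr = tree.arrays() if isinstance(tree, Tree) else tree
    states = np.empty(masks.shape, dtype=np.int8)
    for i in arr.preorder:
        m = masks[i]
        single = np.where(m == 0b10, 1, 0).astype(np.int8)  # singleton value
        tie = m == _BOTH
        if i == arr.root:
            if root_tie == "absent":
                states[i] = np.where(tie, 0, single)
            else:
                states[i] = np.where(tie, UNCERTAIN, single)
        else:
            p = states[arr.parent[i]]
            keep = (p >= 0) & (((m >> p.clip(min=0)) & 1) == 1)
            # parent state not in the set => the set is the other singleton;
            # uncertain parent falls back to the set element (0 on a tie)
            fallback = np.where(tie, 0, single).astype(np.int8)
            states[i] = np.where(keep, p, fallback)
    return states


def events_matrix(tree: Tree | TreeArrays, states: np.ndarray) -> np.ndarray:
    """Per-branch gain/loss events from a full node-state array.

    Rows are branches indexed by their child node (postorder, root row kept
    as all-zero for alignment); entries are +1 gain, -1 loss, 0 otherwise.
    A branch whose parent or child state is uncertain carries no event.
    """
    arr = tree.arrays() if isinstance(tree, Tree) else tree
    events = np.zeros(states.shape, dtype=np.int8)
    nonroot = np.arange(arr.n_nodes) != arr.root
    child = states[nonroot]
    parent = states[arr.parent[nonroot]]
    known = (child != UNCERTAIN) & (parent != UNCERTAIN)
    ev = np.where(known & (parent == 0) & (child == 1), 1, 0) + np.where(
        known & (parent == 1) & (child == 0), -1, 0
    )
    events[nonroot] = ev.astype(np.int8)
    return events


# -- per-column conveniences (dict in, dict out) ------------------------------


def fitch(tree: Tree, column: dict[str, int]):
    """Fitch sets and score for one OG column given as {leaf name: 0/1}.

    Returns ``(sets, score)`` where sets maps node id -> frozenset of states.
    """
    arr = tree.arrays()
    try:
        col = np.array([[column[name]] for name in arr.leaf_ids], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"missing leaf state for {exc.args[0]!r}") from exc
    masks, scores = fitch_matrix(arr, col)
    decode = {0b01: frozenset({0}), 0b10: frozenset({1}), _BOTH: frozenset({0, 1})}
    sets = {arr.node_ids[i]: decode[int(masks[i, 0])] for i in range(arr.n_nodes)}
    return sets, int(scores[0])


def acctran(tree: Tree, column: dict[str, int], root_tie: str = "absent") -> dict[str, int]:
    """One minimum-change labelling (node id -> state) for a single column."""
    arr = tree.arrays()
    col = np.array([[column[name]] for name in arr.leaf_ids], dtype=np.int8)
    masks, _ = fitch_matrix(arr, col)
    states = acctran_matrix(arr, masks, root_tie=root_tie)
    return {arr.node_ids[i]: int(states[i, 0]) for i in range(arr.n_nodes)}


def states_to_events(tree: Tree, anc: dict[str, int]) -> dict[str, int]:
    """Branch events (child node id -> +1/-1/0) from a full node labelling."""
    arr = tree.arrays()
    states = np.array([[anc[name]] for name in arr.node_ids], dtype=np.int8)
    events = events_matrix(arr, states)
    return {
        arr.node_ids[i]: int(events[i, 0])
        for i in range(arr.n_nodes)
        if i != arr.root
    }


def reconstruct(
    tree: Tree, profile: pd.DataFrame, root_tie: str = "absent"
) -> pd.DataFrame:
    """ACCTRAN ancestral states for every OG column of a profile.

    Returns a nodes x OGs frame (all tree nodes, postorder) with entries in
    {0, 1, :data:`UNCERTAIN`}; leaf rows equal the observed profile.
    """
    aligned = align_profile(tree, profile)
    arr = tree.arrays()
    cols = aligned.loc[arr.leaf_ids].to_numpy(dtype=np.int8)
    masks, _ = fitch_matrix(arr, cols)
    states = acctran_matrix(arr, masks, root_tie=root_tie)
    return pd.DataFrame(states, index=arr.node_ids, columns=aligned.columns)
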