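"""Genome-count profiling methods: naive, RLE, CWA and ASA.

All four score an OG pair through a 2x2 contingency table of joint
presence/absence states (11, 10, 01, 00) followed by Fisher's exact test;
they differ in how genomes sharing a state by descent are down-weighted.

* naive       — every genome counts 1 (phylogeny ignored).
* RLE         — consecutive identical joint states along the tree's leaf
                order collapse to one run each; depends on branch rotation.
* CWA         — each maximal monophyletic clade of one joint state counts 1;
                rotation-invariant but blind to branch lengths.
* ASA         — the tree is cut into maximal constant-state subtrees at the
                reconstructed ancestral joint states; the genome count M of a
                subtree is corrected by the ratio of its total branch length
                to the branch length of the equivalent star tree,

                    Mc = M * sum(b_n) / sum(b_n * l_n),   n over the subtree,

                where b_n is the branch above node n and l_n the number of
                subtree leaves under n.  The four per-state sums of Mc are
                rounded up to integers before the exact test.  The
                "unweighted" variant counts each subtree as 1 instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exact_test import fisher
from .phylo_io import UNCERTAIN, Tree, TreeArrays

__all__ = [
    "JOINT_STATES",
    "SubtreeBlock",
    "joint_code",
    "naive_counts",
    "rle_counts",
    "cwa_counts",
    "asa_decompose",
    "asa_correct",
    "asa_counts",
    "contingency_test",
]

#: joint-state labels in cell order (c11, c10, c01, c00)
JOINT_STATES = ("11", "10", "01", "00")

# integer coding: 2*state1 + state2 -> index into JOINT_STATES cells
_CODE_TO_CELL = {3: 0, 2: 1, 1: 2, 0: 3}
_CEIL_EPS = 1e-9


def joint_code(s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
    """Joint-state codes 2*s1 + s2; :data:`UNCERTAIN` if either is uncertain."""
    s1 = np.asarray(s1, dtype=np.int8)
    s2 = np.asarray(s2, dtype=np.int8)
    code = (2 * s1 + s2).astype(np.int8)
    code[(s1 == UNCERTAIN) | (s2 == UNCERTAIN)] = UNCERTAIN
    return code


def _cells_from_codes(codes: np.ndarray, weights: np.ndarray | None = None) -> tuple:
    cells = [0.0, 0.0, 0.0, 0.0]
    for code, cell in _CODE_TO_CELL.items():
        mask = codes == code
        cells[cell] = float(mask.sum()) if weights is None else float(weights[mask].sum())
    return tuple(cells)


def naive_counts(s1: np.ndarray, s2: np.ndarray) -> tuple[int, int, int, int]:
    """Contingency cells (c11, c10, c01, c00) by plain genome tally."""
    c = _cells_from_codes(joint_code(s1, s2))
    return tuple(int(x) for x in c)


def rle_counts(tree: Tree, s1, s2) -> tuple[int, int, int, int]:
    """Run-length-encoded cells: one count per run of identical joint states
    along the depth-first leaf order.  ``s1``/``s2`` are mappings or aligned
    vectors in ``tree.leaf_names()`` order.
    """
    v1, v2 = _as_leaf_vectors(tree, s1, s2)
    codes = joint_code(v1, v2)
    starts = np.ones(len(codes), dtype=bool)
    starts[1:] = codes[1:] != codes[:-1]
    return tuple(int(x) for x in _cells_from_codes(codes[starts]))


def _as_leaf_vectors(tree: Tree, s1, s2) -> tuple[np.ndarray, np.ndarray]:
    names = tree.leaf_names()
    if hasattr(s1, "__getitem__") and not isinstance(s1, (np.ndarray, list, tuple)):
        v1 = np.array([s1[n] for n in names], dtype=np.int8)
        v2 = np.array([s2[n] for n in names], dtype=np.int8)
    else:
        v1 = np.asarray(s1, dtype=np.int8)
        v2 = np.asarray(s2, dtype=np.int8)
        if len(v1) != len(names):
            raise ValueError("leaf-state vector length does not match tree")
    return v1, v2


def cwa_counts(tree: Tree, s1, s2) -> tuple[int, int, int, int]:
    """Clade-wise adjusted cells: each maximal clade whose leaves all share
    one joint state counts once; paraphyletic state-sharing groups are not
    merged.  Rotation-invariant by construction.
    """
    v1, v2 = _as_leaf_vectors(tree, s1, s2)
    arr = tree.arrays()
    codes = np.full(arr.n_nodes, UNCERTAIN, dtype=np.int8)
    uniform = np.zeros(arr.n_nodes, dtype=bool)
    leaf_codes = joint_code(v1, v2)
    # leaf vectors follow leaf_names() (preorder); map onto postorder slots
    pre_leaf = [i for i in arr.preorder if arr.is_leaf[i]]
    codes[pre_leaf] = leaf_codes
    uniform[arr.is_leaf] = True
    for i in np.flatnonzero(~arr.is_leaf):
        kids = arr.children[i]
        if all(uniform[k] for k in kids) and len({int(codes[k]) for k in kids}) == 1:
            uniform[i] = True
            codes[i] = codes[kids[0]]
    # maximal uniform clades: uniform node whose parent clade is not uniform
    # with the same state
    cells = [0, 0, 0, 0]
    for i in range(arr.n_nodes):
        if not uniform[i]:
            continue
        p = arr.parent[i]
        if p != -1 and uniform[p] and codes[p] == codes[i]:
            continue
        cells[_CODE_TO_CELL[int(codes[i])]] += 1
    return tuple(cells)


# ---------------------------------------------------------------------------
# Ancestral State Adjustment
# ---------------------------------------------------------------------------


@dataclass
class SubtreeBlock:
    """A maximal constant-joint-state subtree of the decomposition."""

    root_id: str
    leaves: list[str]
    joint: str  # one of JOINT_STATES
    node_ids: list[str]  # all member nodes (block root included)

    @property
    def M(self) -> int:
        return len(self.leaves)


def _component_roots(arr: TreeArrays, codes: np.ndarray) -> np.ndarray:
    """Per-node component root index under same-state connectivity.

    A node joins its parent's component iff both share the same certain
    joint state; uncertain nodes are isolated (leaves are never uncertain).
    """
    comp = np.empty(arr.n_nodes, dtype=np.int64)
    for i in arr.preorder:
        p = arr.parent[i]
        if p != -1 and codes[i] != UNCERTAIN and codes[i] == codes[p]:
            comp[i] = comp[p]
        else:
            comp[i] = i
    return comp


def asa_decompose(tree: Tree, node_states1, node_states2) -> list[SubtreeBlock]:
    """Cut the tree into maximal subtrees of constant joint ancestral state.

    ``node_states1``/``node_states2`` map node id -> state (0/1/uncertain)
    for the two OGs, or are postorder-indexed vectors.  Each leaf traces back
    toward the root while the joint state is unchanged and certain; leaves
    stopping at the same ancestor form one block.  Every leaf belongs to
    exactly one block.
    """
    arr = tree.arrays()
    s1 = _as_node_vector(arr, node_states1)
    s2 = _as_node_vector(arr, node_states2)
    if np.any((s1[arr.is_leaf] == UNCERTAIN) | (s2[arr.is_leaf] == UNCERTAIN)):
        raise ValueError("leaf joint states must be certain")
    codes = joint_code(s1, s2)
    comp = _component_roots(arr, codes)
    l = _member_leaf_counts(arr, comp)
    members: dict[int, list[int]] = {}
    for i in range(arr.n_nodes):
        if l[i] > 0:  # only nodes on a leaf -> block-root trace-back path
            members.setdefault(int(comp[i]), []).append(i)
    blocks = []
    for root_idx in sorted(members):
        idxs = members[root_idx]
        leaf_ids = [arr.node_ids[i] for i in idxs if arr.is_leaf[i]]
        blocks.append(
            SubtreeBlock(
                root_id=arr.node_ids[root_idx],
                leaves=leaf_ids,
                joint=JOINT_STATES[_CODE_TO_CELL[int(codes[root_idx])]],
                node_ids=[arr.node_ids[i] for i in idxs],
            )
        )
    return blocks


def _as_node_vector(arr: TreeArrays, states) -> np.ndarray:
    if isinstance(states, np.ndarray):
        if len(states) != arr.n_nodes:
            raise ValueError("node-state vector length does not match tree")
        return states.astype(np.int8)
    return np.array([states[name] for name in arr.node_ids], dtype=np.int8)


def asa_correct(block: SubtreeBlock, tree: Tree, include_stem: bool = True) -> float:
    """Corrected genome count Mc of one subtree block.

    Mc = M * sum(b_n) / sum(b_n * l_n) over the block's nodes; b_n is the
    branch above node n (the block root contributes its stem branch in the
    full tree, 0 at the tree root) and l_n counts block leaves at or below n.
    ``include_stem=False`` drops the block root's stem from both sums.
    Degenerate all-zero branch sums fall back to Mc = M with a warning.
    """
    arr = tree.arrays()
    idx = {name: i for i, name in enumerate(arr.node_ids)}
    member = set(block.node_ids)
    leafset = set(block.leaves)
    l = {}
    num = 0.0
    den = 0.0
    for node in tree.postorder():
        if node.id not in member:
            continue
        ln = (1 if node.id in leafset else 0) + sum(
            l.get(c.id, 0) for c in node.children if c.id in member
        )
        l[node.id] = ln
        b = arr.length[idx[node.id]]
        if node.id == block.root_id and not include_stem:
            b = 0.0
        num += b
        den += b * ln
    if den <= 0.0:
        warnings.warn(
            f"block at {block.root_id!r} has zero total branch length; "
            "Mc falls back to the raw genome count",
            stacklevel=2,
        )
        return float(block.M)
    return block.M * num / den


def _member_leaf_counts(arr: TreeArrays, comp: np.ndarray) -> np.ndarray:
    """l_n: same-component leaves at or below each node (postorder sweep)."""
    l = np.zeros(arr.n_nodes, dtype=np.int64)
    for i in range(arr.n_nodes):  # postorder index order
        ln = 1 if arr.is_leaf[i] else 0
        for k in arr.children[i]:
            if comp[k] == comp[i]:
                ln += l[k]
        l[i] = ln
    return l


def _asa_cell_sums(
    arr: TreeArrays, codes: np.ndarray, weighted: bool, include_stem: bool
) -> list[float]:
    """Per-joint-state sums of Mc (or block counts) in one postorder sweep."""
    comp = _component_roots(arr, codes)
    l = _member_leaf_counts(arr, comp)
    num = np.zeros(arr.n_nodes, dtype=np.float64)
    den = np.zeros(arr.n_nodes, dtype=np.float64)
    for i in range(arr.n_nodes):
        ln = l[i]
        if ln == 0:
            # same-state branch dangling off the subtree with no member
            # leaves beneath: not on any trace-back path, so not counted
            continue
        b = arr.length[i]
        if not include_stem and comp[i] == i:
            b = 0.0
        num[comp[i]] += b
        den[comp[i]] += b * ln
    sums = [0.0, 0.0, 0.0, 0.0]
    degenerate = 0
    for r in np.flatnonzero(comp == np.arange(arr.n_nodes)):
        M = l[r]
        if M == 0:  # leafless internal component
            continue
        cell = _CODE_TO_CELL[int(codes[r])]
        if not weighted:
            sums[cell] += 1
        elif den[r] <= 0.0:
            degenerate += 1
            sums[cell] += float(M)
        else:
            sums[cell] += M * num[r] / den[r]
    if degenerate:
        warnings.warn(
            f"{degenerate} block(s) with zero total branch length; "
            "Mc fell back to the raw genome count",
            stacklevel=3,
        )
    return sums


def asa_counts(
    tree: Tree | TreeArrays,
    node_states1,
    node_states2,
    weighted: bool = True,
    include_stem: bool = True,
) -> tuple[int, int, int, int]:
    """ASA contingency cells: per joint state, the ceiling of the summed
    corrected counts Mc (weighted) or the number of blocks (unweighted).
    """
    arr = tree.arrays() if isinstance(tree, Tree) else tree
    s1 = _as_node_vector(arr, node_states1)
    s2 = _as_node_vector(arr, node_states2)
    if np.any((s1[arr.is_leaf] == UNCERTAIN) | (s2[arr.is_leaf] == UNCERTAIN)):
        raise ValueError("leaf joint states must be certain")
    codes = joint_code(s1, s2)
    sums = _asa_cell_sums(arr, codes, weighted=weighted, include_stem=include_stem)
    return tuple(int(np.ceil(s - _CEIL_EPS)) if s > 0 else 0 for s in sums)


# ---------------------------------------------------------------------------
# shared test step
# ---------------------------------------------------------------------------


def contingency_test(
    c11: float, c10: float, c01: float, c00: float, alternative: str = "two_sided"
) -> tuple[float, int]:
    """Fisher p-value and association sign (+1 co-occurrence, -1 avoidance).

    The sign is that of the cross-product difference c11*c00 - c10*c01.
    """
    p = fisher(int(c11), int(c10), int(c01), int(c00), alternative=alternative)
    diff = c11 * c00 - c10 * c01
    sign = 0 if diff == 0 else (1 if diff > 0 else -1)
    return p, sign
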