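"""Rooted-tree, profile and ancestral-state I/O.

Trees are rooted phylogenies with branch lengths; leaves are genomes.
Profiles are genomes x ortholog-group (OG) binary matrices.  Ancestral-state
tables assign each internal node a per-OG state in {0, 1, uncertain}, e.g. as
produced by pastML's marginal reconstruction (a node reported with more than
one possible state is uncertain).

The tree container is deliberately lightweight: the profiling methods need
deterministic node identifiers, stored child order (run-length encoding and
cotransitions depend on it), in-place child rotation, and fast array-indexed
traversals — newick text is parsed through dendropy and converted.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Tree",
    "TreeNode",
    "TreeError",
    "UNCERTAIN",
    "parse_newick",
    "read_tree",
    "write_newick",
    "read_profile",
    "write_profile",
    "read_ancestral_table",
    "write_ancestral_table",
]

#: integer code for an uncertain ancestral state (0 and 1 are themselves)
UNCERTAIN: int = -1

DEFAULT_BRANCH_LENGTH = 1.0


class TreeError(ValueError):
    """Raised for malformed trees or inconsistent tree/profile inputs."""


@dataclass
class TreeNode:
    id: str
    parent: "TreeNode | None" = None
    children: list["TreeNode"] = field(default_factory=list)
    length: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.id!r}, n_children={len(self.children)})"


class Tree:
    """Rooted tree with named leaves and stable internal-node identifiers.

    Node ids are unique strings.  Unnamed internal nodes are auto-labelled
    ``N<k>`` where ``k`` is the node's post-order rank among internal nodes;
    the labelling is deterministic so externally produced ancestral-state
    tables can be regenerated against the same tree.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._index()

    # -- construction helpers -------------------------------------------------

    def _index(self) -> None:
        self.nodes: dict[str, TreeNode] = {}
        for node in self.postorder():
            if node.id in self.nodes:
                raise TreeError(f"duplicate node id {node.id!r}")
            self.nodes[node.id] = node
        leaves = self.leaves()
        if len({n.id for n in leaves}) != len(leaves):  # pragma: no cover
            raise TreeError("duplicate leaf names")

    # -- traversal ------------------------------------------------------------

    def postorder(self) -> Iterator[TreeNode]:
        stack: list[tuple[TreeNode, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        """Leaf names in depth-first order respecting stored child order.

        This is the genome ordering used by run-length encoding and
        cotransitions; it changes when the tree is rotated.
        """
        return [n.id for n in self.preorder() if n.is_leaf]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.postorder() if not n.is_leaf]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    # -- manipulation ---------------------------------------------------------

    def rotate(self, node_id: str) -> "Tree":
        """Reverse the child order of an internal node, in place.

        Rotation changes how the tree is drawn (and hence the leaf order)
        but not its topology, branch lengths or any leaf-to-leaf path.
        Returns self for chaining.
        """
        node = self.nodes[node_id]
        if node.is_leaf:
            raise TreeError(f"cannot rotate leaf node {node_id!r}")
        node.children.reverse()
        return self

    def resolve_polytomies(self) -> "Tree":
        """Make the tree binary by left-fold insertion of zero-length nodes.

        A node with children ``[c1, c2, c3, ...]`` becomes a ladder
        ``((c1, c2), c3), ...`` where each inserted node has branch length 0.
        Leaf pairwise path lengths are unchanged.  In place; returns self.
        """
        counter = 0
        for node in list(self.postorder()):
            while len(node.children) > 2:
                left, right = node.children[0], node.children[1]
                merged = TreeNode(id=f"{node.id}.p{counter}", parent=node, length=0.0)
                counter += 1
                merged.children = [left, right]
                left.parent = merged
                right.parent = merged
                node.children = [merged] + node.children[2:]
        self._index()
        return self

    def copy(self) -> "Tree":
        def clone(node: TreeNode, parent: TreeNode | None) -> TreeNode:
            new = TreeNode(id=node.id, parent=parent, length=node.length)
            new.children = [clone(c, new) for c in node.children]
            return new

        return Tree(clone(self.root, None))

    # -- array views used by the numeric modules ------------------------------

    def postorder_index(self) -> dict[str, int]:
        return {n.id: i for i, n in enumerate(self.postorder())}

    def arrays(self) -> "TreeArrays":
        return TreeArrays(self)

    def path_length_matrix(self) -> pd.DataFrame:
        """Leaf-to-leaf path lengths (brute force; used by invariance tests)."""
        names = sorted(n.id for n in self.leaves())
        depth: dict[str, float] = {}
        anc: dict[str, list[str]] = {}
        for node in self.preorder():
            d = 0.0 if node.parent is None else depth[node.parent.id] + node.length
            depth[node.id] = d
            chain = [] if node.parent is None else anc[node.parent.id] + [node.parent.id]
            anc[node.id] = chain
        out = pd.DataFrame(0.0, index=names, columns=names)
        for a in names:
            for b in names:
                if a == b:
                    continue
                sa, sb = set(anc[a] + [a]), set(anc[b] + [b])
                mrca = max((n for n in sa & sb), key=lambda n: depth[n])
                out.loc[a, b] = depth[a] + depth[b] - 2 * depth[mrca]
        return out


class TreeArrays:
    """Flat postorder-indexed view of a tree for vectorised algorithms."""

    def __init__(self, tree: Tree):
        order = list(tree.postorder())
        idx = {n.id: i for i, n in enumerate(order)}
        self.node_ids = [n.id for n in order]
        self.parent = np.array(
            [idx[n.parent.id] if n.parent is not None else -1 for n in order],
            dtype=np.int64,
        )
        self.length = np.array([n.length for n in order], dtype=np.float64)
        self.is_leaf = np.array([n.is_leaf for n in order], dtype=bool)
        self.children = [[idx[c.id] for c in n.children] for n in order]
        self.root = idx[tree.root.id]
        self.leaf_ids = [n.id for n in order if n.is_leaf]
        # preorder as indices (root first)
        self.preorder = np.empty(len(order), dtype=np.int64)
        for i, node in enumerate(tree.preorder()):
            self.preorder[i] = idx[node.id]

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------


def parse_newick(
    text: str,
    default_branch_length: float = DEFAULT_BRANCH_LENGTH,
    resolve_polytomies: bool = False,
) -> Tree:
    """Parse a rooted newick string into a :class:`Tree`.

    Child order follows the file.  Unnamed internal nodes get deterministic
    ``N<k>`` labels by post-order rank.  Missing branch lengths default to
    ``default_branch_length`` (with a warning) because the branch-length
    weighted methods require them.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    except Exception as exc:
        raise TreeError(f"malformed newick: {exc}") from exc

    missing = 0

    def convert(dnode, parent: TreeNode | None) -> TreeNode:
        nonlocal missing
        label = None
        if dnode.taxon is not None and dnode.taxon.label:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        length = dnode.edge.length
        if length is None:
            if parent is not None:
                missing += 1
            length = 0.0 if parent is None else default_branch_length
        node = TreeNode(id=label or "", parent=parent, length=float(length))
        node.children = [convert(c, node) for c in dnode.child_nodes()]
        return node

    root = convert(dtree.seed_node, None)

    # deterministic N<k> labels for unnamed internal nodes, postorder rank
    counter = 0
    names_seen = set()
    post: list[TreeNode] = []

    def collect(node: TreeNode) -> None:
        for c in node.children:
            collect(c)
        post.append(node)

    collect(root)
    for node in post:
        if node.id:
            names_seen.add(node.id)
    for node in post:
        if not node.children and not node.id:
            raise TreeError("unnamed leaf in newick input")
        if node.children and not node.id:
            while f"N{counter}" in names_seen:
                counter += 1
            node.id = f"N{counter}"
            counter += 1

    leaf_names = [n.id for n in post if not n.children]
    if len(set(leaf_names)) != len(leaf_names):
        dupes = sorted({x for x in leaf_names if leaf_names.count(x) > 1})
        raise TreeError(f"duplicate leaf names: {dupes}")
    if missing:
        warnings.warn(
            f"{missing} branch length(s) missing; defaulted to "
            f"{default_branch_length}",
            stacklevel=2,
        )
    if len(leaf_names) == 1:
        warnings.warn("single-leaf tree", stacklevel=2)

    tree = Tree(root)
    if resolve_polytomies and not tree.is_binary():
        tree.resolve_polytomies()
    return tree


def read_tree(path, **kwargs) -> Tree:
    with open(path) as fh:
        return parse_newick(fh.read(), **kwargs)


def write_newick(tree: Tree, path=None, internal_labels: bool = True) -> str:
    """Serialise to newick; round-trips topology, labels and lengths."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            body = node.id
        else:
            inner = ",".join(fmt(c) for c in node.children)
            body = f"({inner}){node.id if internal_labels else ''}"
        if node.parent is None:
            return body
        return f"{body}:{node.length:.10g}"

    text = fmt(tree.root) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


def read_profile(path) -> pd.DataFrame:
    """Read a genomes x OGs presence/absence TSV.

    Row 1 holds OG ids, column 1 genome ids; entries must be 0/1.
    Comment lines starting with ``#`` are skipped.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    values = df.to_numpy()
    if df.isna().any().any():
        raise ValueError("profile contains missing entries")
    if not np.isin(values, (0, 1)).all():
        bad = sorted(set(np.unique(values)) - {0, 1})
        raise ValueError(f"profile entries must be 0/1; found {bad}")
    df = df.astype(np.int8)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_profile(profile: pd.DataFrame, path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        profile.to_csv(fh, sep="\t")


def align_profile(tree: Tree, profile: pd.DataFrame) -> pd.DataFrame:
    """Reorder profile rows to the tree's leaf order; mismatch is a hard error."""
    leaves = tree.leaf_names()
    missing_in_profile = sorted(set(leaves) - set(profile.index))
    missing_in_tree = sorted(set(profile.index) - set(leaves))
    if missing_in_profile or missing_in_tree:
        raise TreeError(
            "tree/profile mismatch; leaves without profile rows: "
            f"{missing_in_profile}; profile rows without leaves: {missing_in_tree}"
        )
    return profile.loc[leaves]


# ---------------------------------------------------------------------------
# ancestral-state tables
# ---------------------------------------------------------------------------


def read_ancestral_table(path, tree: Tree, profile: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a per-node ancestral-state TSV into a nodes x OGs frame.

    Column 1 is the node id; remaining columns are OGs.  A cell ``0|1`` (or
    any multi-valued entry) denotes uncertainty and maps to :data:`UNCERTAIN`.
    The pastML combined-table layout, where an ambiguous node is repeated on
    several rows with alternative states, is also accepted.  Leaf rows must
    agree with the profile when one is supplied.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    node_col = raw.columns[0]
    ogs = list(raw.columns[1:])
    states: dict[str, np.ndarray] = {}
    for node_id, group in raw.groupby(node_col, sort=False):
        if node_id not in tree.nodes:
            raise TreeError(f"ancestral table references unknown node {node_id!r}")
        row = np.empty(len(ogs), dtype=np.int8)
        for j, og in enumerate(ogs):
            vals = set()
            for cell in group[og]:
                if pd.isna(cell):
                    continue
                vals.update(part.strip() for part in str(cell).split("|"))
            vals.discard("")
            if vals == {"0"}:
                row[j] = 0
            elif vals == {"1"}:
                row[j] = 1
            elif vals <= {"0", "1"} and len(vals) == 2:
                row[j] = UNCERTAIN
            else:
                raise ValueError(
                    f"invalid ancestral state {sorted(vals)} at node {node_id!r}, OG {og!r}"
                )
        states[str(node_id)] = row

    table = pd.DataFrame.from_dict(states, orient="index", columns=ogs).astype(np.int8)
    missing = [n.id for n in tree.postorder() if n.id not in table.index and not n.is_leaf]
    if missing:
        raise TreeError(f"ancestral table missing internal nodes: {missing[:5]}...")

    if profile is not None:
        common_ogs = [og for og in ogs if og in profile.columns]
        for leaf in tree.leaf_names():
            if leaf not in table.index:
                continue
            for og in common_ogs:
                anc = table.at[leaf, og]
                obs = profile.at[leaf, og]
                if anc != UNCERTAIN and anc != obs:
                    raise ValueError(
                        f"leaf state conflicts with profile at ({leaf!r}, {og!r})"
                    )
    return table


def write_ancestral_table(states: pd.DataFrame, path) -> None:
    """Write a nodes x OGs state frame as TSV, uncertain cells as ``0|1``."""
    out = states.astype(object).replace(UNCERTAIN, "0|1")
    out.index.name = "node"
    out.to_csv(path, sep="\t")


def states_frame_to_array(tree: Tree, states: pd.DataFrame, ogs: Sequence[str]) -> np.ndarray:
    """Postorder-indexed (nodes x OGs) int8 state array from a state frame."""
    arr = tree.arrays()
    out = np.empty((arr.n_nodes, len(ogs)), dtype=np.int8)
    for i, node_id in enumerate(arr.node_ids):
        if node_id not in states.index:
            raise TreeError(f"no ancestral states for node {node_id!r}")
        out[i] = states.loc[node_id, list(ogs)].to_numpy(dtype=np.int8)
    return out
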