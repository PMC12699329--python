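import itertools

import numpy as np
import pytest

from corgias import parse_newick
from corgias.phylo_io import Tree, TreeNode


@pytest.fixture
def quartet():
    """((A,B),(C,D)) with unit branch lengths."""
    return parse_newick("((A:1,B:1)L:1,(C:1,D:1)R:1);")


@pytest.fixture
def six_leaf_witness():
    """Two separated same-state clades: the RLE/cotransitions rotation witness."""
    return parse_newick("((A:1,B:1):1,((C:1,D:1):1,(E:1,F:1):1):1);")


def random_binary_tree(rng, n_leaves, max_length=2.0) -> Tree:
    """Random topology by sequential leaf attachment; random branch lengths."""
    names = [f"L{i}" for i in range(n_leaves)]
    nodes = [TreeNode(id=names[0]), TreeNode(id=names[1])]
    root = TreeNode(id="root")
    root.children = nodes
    for n in nodes:
        n.parent = root
    leaves = list(nodes)
    for i in range(2, n_leaves):
        target = leaves[int(rng.integers(len(leaves)))]
        parent = target.parent
        inner = TreeNode(id=f"I{i}", parent=parent)
        new_leaf = TreeNode(id=names[i], parent=inner)
        inner.children = [target, new_leaf]
        target.parent = inner
        parent.children[parent.children.index(target)] = inner
        leaves.append(new_leaf)
    tree = Tree(root)
    for node in tree.postorder():
        if node.parent is not None:
            node.length = float(rng.uniform(0.05, max_length))
    return tree


def exhaustive_parsimony(tree: Tree, column: dict) -> int:
    """Minimal change count by enumerating every internal labelling."""
    internals = [n.id for n in tree.internal_nodes()]
    best = None
    for assign in itertools.product((0, 1), repeat=len(internals)):
        states = dict(column)
        states.update(zip(internals, assign))
        changes = sum(
            states[n.id] != states[n.parent.id]
            for n in tree.postorder()
            if n.parent is not None
        )
        best = changes if best is None else min(best, changes)
    return best


def loop_concordance(u: np.ndarray, v: np.ndarray) -> int:
    """Double-loop concordance-minus-discordance tally (oracle for E'E)."""
    k = 0
    for a, b in zip(u.tolist(), v.tolist()):
        if a != 0 and b != 0:
            k += 1 if a == b else -1
    return k
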