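"""Synthetic co-evolution data: Yule trees and coupled binary-trait pairs.

The generator emulates the study conditions the profiling methods are meant
for: a pure-birth species tree and pairs of OGs evolving as a joint 4-state
continuous-time Markov chain in which each OG's gain and loss rates depend
on the partner's current state,

    gain_i = exp(alpha_i + beta_i + c * x_partner)
    loss_i = exp(alpha_i - beta_i - c * x_partner)

so alpha_i sets the overall evolutionary speed, beta_i is half the log
gain/loss asymmetry, and the interaction coefficient c couples the two OGs
(c = 0 is the independent null; positive c makes presence attract presence).
Parameters of a dataset are drawn per pair: c ~ U(0.2, 0.75) for co-evolved
pairs and 0 otherwise, alpha ~ U(-0.5, 1), beta ~ U(-0.5, 0.3), with
co-evolved : independent pairs at 1:99 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo_io import Tree, TreeNode

__all__ = ["PairParams", "yule_tree", "simulate_pair", "generate_dataset"]

_C_RANGE = (0.2, 0.75)
_ALPHA_RANGE = (-0.5, 1.0)
_BETA_RANGE = (-0.5, 0.3)
DEFAULT_POSITIVE_FRACTION = 0.01


@dataclass
class PairParams:
    """Rates of one interacting OG pair."""

    c: float
    alpha1: float
    alpha2: float
    beta1: float
    beta2: float

    def rates(self, og: int, partner_state: int) -> tuple[float, float]:
        """(gain, loss) rates of OG ``og`` (0/1) given the partner's state."""
        alpha = self.alpha1 if og == 0 else self.alpha2
        beta = self.beta1 if og == 0 else self.beta2
        with np.errstate(over="ignore"):
            gain = np.exp(alpha + beta + self.c * partner_state)
            loss = np.exp(alpha - beta - self.c * partner_state)
        if not (np.isfinite(gain) and np.isfinite(loss)):
            raise ValueError("non-finite transition rate")
        return float(gain), float(loss)

    def stationary_presence(self, og: int, partner_state: int = 0) -> float:
        """P(present) of the single-OG chain at a fixed partner state."""
        gain, loss = self.rates(og, partner_state)
        return gain / (gain + loss)


def yule_tree(n_leaves: int, birth_rate: float = 1.0, seed=None) -> Tree:
    """Pure-birth (Yule) tree with ``n_leaves`` tips.

    Lineages split at exponential waiting times with total rate
    birth_rate * (#active lineages); a final waiting period at the full tip
    count sets the terminal branch segment, so the tree is ultrametric.
    Expected total branch length is (n_leaves - 1) / birth_rate.
    """
    if n_leaves < 2:
        raise ValueError("a Yule tree needs at least 2 leaves")
    rng = np.random.default_rng(seed)
    root = TreeNode(id="__pending0__", length=0.0)
    active: list[TreeNode] = [root]
    birth_time = {id(root): 0.0}
    counter = 1
    now = 0.0
    while len(active) < n_leaves:
        now += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = int(rng.integers(len(active)))
        parent = active[idx]
        # the initial waiting period would be the root's incoming edge
        parent.length = 0.0 if parent.parent is None else now - birth_time[id(parent)]
        kids = []
        for _ in range(2):
            child = TreeNode(id=f"__pending{counter}__", parent=parent)
            counter += 1
            birth_time[id(child)] = now
            kids.append(child)
        parent.children = kids
        active[idx] = kids[0]
        active.append(kids[1])
    now += rng.exponential(1.0 / (birth_rate * len(active)))
    for tip in active:
        tip.length = now - birth_time[id(tip)]

    # name leaves G0.. in depth-first order; internals get postorder N labels
    tree = Tree(root)
    for i, node in enumerate(tree.preorder()):
        node.id = f"__tmp{i}__"
    leaf_counter = 0
    for node in tree.preorder():
        if node.is_leaf:
            node.id = f"G{leaf_counter:04d}"
            leaf_counter += 1
    internal_counter = 0
    for node in tree.postorder():
        if not node.is_leaf:
            node.id = f"N{internal_counter}"
            internal_counter += 1
    return Tree(root)


def _evolve_branch(state, params: PairParams, duration: float, rng) -> tuple:
    """Exact event-time simulation of the joint chain along one branch."""
    x1, x2 = state
    t = 0.0
    while True:
        g1, l1 = params.rates(0, x2)
        g2, l2 = params.rates(1, x1)
        r1 = l1 if x1 else g1
        r2 = l2 if x2 else g2
        total = r1 + r2
        t += rng.exponential(1.0 / total)
        if t >= duration:
            return x1, x2
        if rng.random() < r1 / total:
            x1 = 1 - x1
        else:
            x2 = 1 - x2


def simulate_pair(
    tree: Tree, params: PairParams, seed=None, root_state: str = "stationary"
):
    """Evolve one interacting OG pair from root to tips.

    The root state is drawn per OG from the single-OG stationary distribution
    at partner state 0 (``root_state="stationary"``) or uniformly
    (``root_state="uniform"``).  Returns two {leaf name: 0/1} mappings.
    """
    rng = np.random.default_rng(seed)
    if root_state == "stationary":
        x1 = int(rng.random() < params.stationary_presence(0))
        x2 = int(rng.random() < params.stationary_presence(1))
    elif root_state == "uniform":
        x1, x2 = int(rng.integers(2)), int(rng.integers(2))
    else:
        raise ValueError(f"unknown root_state {root_state!r}")

    states = {tree.root.id: (x1, x2)}
    for node in tree.preorder():
        if node.parent is None:
            continue
        states[node.id] = _evolve_branch(
            states[node.parent.id], params, node.length, rng
        )
    col1 = {n.id: states[n.id][0] for n in tree.leaves()}
    col2 = {n.id: states[n.id][1] for n in tree.leaves()}
    return col1, col2


def sample_params(rng, coevolved: bool) -> PairParams:
    """Draw one pair's parameters from the study distributions."""
    return PairParams(
        c=float(rng.uniform(*_C_RANGE)) if coevolved else 0.0,
        alpha1=float(rng.uniform(*_ALPHA_RANGE)),
        alpha2=float(rng.uniform(*_ALPHA_RANGE)),
        beta1=float(rng.uniform(*_BETA_RANGE)),
        beta2=float(rng.uniform(*_BETA_RANGE)),
    )


def generate_dataset(
    tree: Tree,
    n_pairs: int,
    positive_fraction: float = DEFAULT_POSITIVE_FRACTION,
    seed=None,
):
    """Simulate a profile of concatenated OG pairs with truth labels.

    The first ``round(n_pairs * positive_fraction)`` pairs are co-evolved
    (c drawn from U(0.2, 0.75)), the rest independent (c = 0); column order
    interleaves pairs as OG0000, OG0001 (pair 0), OG0002, OG0003 (pair 1), …

    Returns ``(profile, truth)``: a genomes x 2*n_pairs presence/absence
    frame and a per-pair frame with columns og1, og2, label, c, alpha1,
    alpha2, beta1, beta2.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    n_pos = int(round(n_pairs * positive_fraction))
    leaves = tree.leaf_names()
    columns: dict[str, list[int]] = {}
    records = []
    for i in range(n_pairs):
        coev = i < n_pos
        params = sample_params(rng, coevolved=coev)
        c1, c2 = simulate_pair(tree, params, seed=rng.integers(2**31))
        og1, og2 = f"OG{2 * i:04d}", f"OG{2 * i + 1:04d}"
        columns[og1] = [c1[g] for g in leaves]
        columns[og2] = [c2[g] for g in leaves]
        records.append(
            {
                "og1": og1,
                "og2": og2,
                "label": int(coev),
                "c": params.c,
                "alpha1": params.alpha1,
                "alpha2": params.alpha2,
                "beta1": params.beta1,
                "beta2": params.beta2,
            }
        )
    profile = pd.DataFrame(columns, index=pd.Index(leaves, name="genome"), dtype=np.int8)
    truth = pd.DataFrame(records)
    return profile, truth
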