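"""Event-based profiling: the simultaneous-evolution test (SEV) and the
leaf-order cotransitions statistic, plus the all-method pair dispatcher.

Both methods score an OG pair through a one-tailed Fisher exact test on

        |k|            t1 - |k|
        t2 - |k|       n - t1 - t2 + |k|

where t1, t2 count the gain/loss events of each OG, k is the number of
concordant minus discordant events shared at the same position, and n is the
population of positions at which events can occur: internal nodes of the
tree for SEV (parsimony never infers the same-direction change on both child
branches of a node, so events live on nodes, not branches) and genomes - 1
for cotransitions (events live in the gaps between adjacent leaves).

k for every pair at once is the Gram matrix E'E of the branch-events (or
gap-events) matrix E with entries in {-1, 0, +1}; a positive k flags
co-evolution, a negative k contrapositive evolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from . import ancestral_parsimony as parsimony
from . import weighted_methods as weighted
from .exact_test import fisher_greater_vec
from .phylo_io import (
    UNCERTAIN,
    Tree,
    TreeError,
    align_profile,
    states_frame_to_array,
)

__all__ = [
    "EventMatrix",
    "PairResult",
    "cotransition_events",
    "sev_events",
    "all_pairs_k",
    "sev_test",
    "run_method",
    "results_to_frame",
    "METHODS",
]

METHODS = ("naive", "rle", "cwa", "asa", "asa_unweighted", "cotransitions", "sev")


@dataclass
class EventMatrix:
    """Signed event matrix: rows are positions (branches keyed by child node
    for SEV, adjacent-leaf gaps for cotransitions), columns are OGs."""

    data: np.ndarray  # (positions x OGs), int8 in {-1, 0, 1}
    row_ids: list[str]
    og_ids: list[str]
    n: int  # exact-test population size

    @property
    def t(self) -> np.ndarray:
        """Per-OG number of gain/loss events."""
        return np.count_nonzero(self.data, axis=0)


@dataclass
class PairResult:
    og1: str
    og2: str
    method: str
    p_value: float
    direction: str  # coevolved / contrapositive / none
    assoc: int  # association sign regardless of significance
    c11: int | None = None
    c10: int | None = None
    c01: int | None = None
    c00: int | None = None
    k: int | None = None
    t1: int | None = None
    t2: int | None = None
    n: int | None = None
    clamped: bool = False


def cotransition_events(tree: Tree, profile: pd.DataFrame) -> EventMatrix:
    """Events in the gaps of the depth-first leaf ordering.

    Gap g holds +1 when OG state goes 0 -> 1 between ordered genomes g and
    g+1, -1 for 1 -> 0, else 0; n = number of genomes - 1.  Depends on the
    stored child order, hence on branch rotation.
    """
    aligned = align_profile(tree, profile)
    mat = aligned.to_numpy(dtype=np.int8)
    events = (mat[1:] - mat[:-1]).astype(np.int8)
    names = list(aligned.index)
    row_ids = [f"{names[i]}|{names[i + 1]}" for i in range(len(names) - 1)]
    return EventMatrix(
        data=events, row_ids=row_ids, og_ids=list(aligned.columns), n=len(names) - 1
    )


def collapse_consecutive(events: EventMatrix) -> EventMatrix:
    """Zero an event when the same OG already changed in the previous gap.

    Approximates the original cotransitions behaviour of ignoring
    consecutive changes; off by default.
    """
    data = events.data.copy()
    for g in range(1, data.shape[0]):
        data[g][data[g - 1] != 0] = 0
    return EventMatrix(data=data, row_ids=events.row_ids, og_ids=events.og_ids, n=events.n)


def sev_events(
    tree: Tree,
    profile: pd.DataFrame,
    states: pd.DataFrame | None = None,
    root_tie: str = "absent",
) -> EventMatrix:
    """Per-branch gain/loss events from ancestral states.

    By default ancestral states come from internal Fitch/ACCTRAN parsimony,
    which guarantees the no-parallel-change constraint of the exact test.
    A user-supplied state table (``states``) overrides parsimony; labellings
    that place the same-direction change on both child branches of a node
    are rejected because they break the test's population size
    n = number of internal nodes.
    """
    if not tree.is_binary():
        raise TreeError("SEV requires a binary tree; resolve polytomies first")
    aligned = align_profile(tree, profile)
    arr = tree.arrays()
    if states is None:
        masks, _ = parsimony.fitch_matrix(
            arr, aligned.loc[arr.leaf_ids].to_numpy(dtype=np.int8)
        )
        node_states = parsimony.acctran_matrix(arr, masks, root_tie=root_tie)
    else:
        node_states = _override_states(tree, arr, aligned, states)
    events = parsimony.events_matrix(arr, node_states)
    _check_no_parallel(arr, events, list(aligned.columns), external=states is not None)
    keep = np.arange(arr.n_nodes) != arr.root
    return EventMatrix(
        data=events[keep],
        row_ids=[arr.node_ids[i] for i in np.flatnonzero(keep)],
        og_ids=list(aligned.columns),
        n=int(np.count_nonzero(~arr.is_leaf)),
    )


def _override_states(tree, arr, aligned, states: pd.DataFrame) -> np.ndarray:
    full = states.copy()
    for leaf in aligned.index:  # fill leaves from the profile when absent
        if leaf not in full.index:
            full.loc[leaf] = aligned.loc[leaf]
    return states_frame_to_array(tree, full, list(aligned.columns))


def _check_no_parallel(arr, events, og_ids, external: bool) -> None:
    for i in np.flatnonzero(~arr.is_leaf):
        kids = arr.children[i]
        if len(kids) != 2:
            continue
        both = (events[kids[0]] != 0) & (events[kids[0]] == events[kids[1]])
        if both.any():
            og = og_ids[int(np.flatnonzero(both)[0])]
            msg = (
                f"parallel same-direction change at node {arr.node_ids[i]!r} "
                f"for OG {og!r} violates the SEV constraint"
            )
            if external:
                raise ValueError(msg)
            raise AssertionError(msg)  # internal parsimony can never do this


def all_pairs_k(events: EventMatrix | np.ndarray) -> np.ndarray:
    """All-versus-all concordance-minus-discordance counts K = E'E.

    K[i, j] = (#positions where both OGs change in the same direction)
            - (#positions where they change in opposite directions);
    the diagonal holds the per-OG event counts t.
    """
    E = events.data if isinstance(events, EventMatrix) else np.asarray(events)
    return (E.astype(np.int32).T @ E.astype(np.int32)).astype(np.int64)


def sev_test(k, t1, t2, n):
    """One-tailed Fisher p-value(s) and direction(s) for event-count tables.

    Accepts scalars or aligned arrays.  p = P(X >= |k|) for hypergeometric X
    with margins (t1, n-t1) x (t2, n-t2) over population n.  When the
    bottom-right cell n - t1 - t2 + |k| is negative (only possible with
    user-supplied non-parsimony states) the observed table lies outside the
    hypergeometric support; |k| is clamped to the most extreme supported
    table and the pair flagged.

    Returns ``(p, direction, clamped)``; direction is the sign of k.
    """
    k = np.asarray(k)
    t1 = np.asarray(t1)
    t2 = np.asarray(t2)
    scalar = k.ndim == 0
    k, t1, t2 = np.atleast_1d(k), np.atleast_1d(t1), np.atleast_1d(t2)
    if np.any(t1 < 0) or np.any(t2 < 0) or n < 0:
        raise ValueError("event counts and population must be nonnegative")
    if np.any(np.abs(k) > np.minimum(t1, t2)):
        raise ValueError("|k| cannot exceed min(t1, t2)")
    lo = np.maximum(0, t1 + t2 - n)
    absk = np.abs(k)
    clamped = absk < lo
    absk = np.maximum(absk, lo)
    p = fisher_greater_vec(absk, t1, t2, n)
    sign = np.sign(k)
    if scalar:
        return float(p[0]), int(sign[0]), bool(clamped[0])
    return p, sign.astype(np.int64), clamped


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------


def run_method(
    tree: Tree,
    profile: pd.DataFrame,
    method: str,
    pairs: list[tuple[str, str]] | None = None,
    states: pd.DataFrame | None = None,
    alpha: float = 0.05,
    alternative: str = "two_sided",
    include_stem: bool = True,
    root_tie: str = "absent",
    collapse: bool = False,
) -> list[PairResult]:
    """Score OG pairs with one of the profiling methods.

    ``pairs`` restricts scoring to the given (og1, og2) tuples; by default
    every unordered pair of profile columns is scored.  ``states`` supplies
    external ancestral states (ASA; optionally SEV).  ``alpha`` is the
    report-time significance threshold deciding the direction label.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    aligned = align_profile(tree, profile)
    ogs = list(aligned.columns)
    if pairs is None:
        pairs = list(combinations(ogs, 2))
    for a, b in pairs:
        if a not in aligned.columns or b not in aligned.columns:
            raise ValueError(f"pair ({a!r}, {b!r}) not in profile")

    if method in ("cotransitions", "sev"):
        return _run_transition(
            tree, aligned, method, pairs, states, alpha, root_tie, collapse
        )
    return _run_weighted(
        tree, aligned, method, pairs, states, alpha, alternative, include_stem, root_tie
    )


def _direction(sign: int, p: float, alpha: float) -> str:
    if p >= alpha or sign == 0:
        return "none"
    return "coevolved" if sign > 0 else "contrapositive"


def _run_transition(tree, aligned, method, pairs, states, alpha, root_tie, collapse):
    if method == "cotransitions":
        ev = cotransition_events(tree, aligned)
        if collapse:
            ev = collapse_consecutive(ev)
    else:
        ev = sev_events(tree, aligned, states=states, root_tie=root_tie)
    col = {og: i for i, og in enumerate(ev.og_ids)}
    i1 = np.array([col[a] for a, _ in pairs], dtype=np.int64)
    i2 = np.array([col[b] for _, b in pairs], dtype=np.int64)
    E = ev.data.astype(np.int32)
    t = ev.t
    # pairwise k without materialising the full Gram matrix when targeted
    if len(pairs) < E.shape[1] ** 2 // 4:
        k = np.einsum("ij,ij->j", E[:, i1], E[:, i2]).astype(np.int64)
    else:
        K = all_pairs_k(ev)
        k = K[i1, i2]
    p, sign, clamped = sev_test(k, t[i1], t[i2], ev.n)
    p, sign, clamped = np.atleast_1d(p), np.atleast_1d(sign), np.atleast_1d(clamped)
    return [
        PairResult(
            og1=a,
            og2=b,
            method=method,
            p_value=float(p[j]),
            direction=_direction(int(sign[j]), float(p[j]), alpha),
            assoc=int(sign[j]),
            k=int(k[j]),
            t1=int(t[i1[j]]),
            t2=int(t[i2[j]]),
            n=ev.n,
            clamped=bool(clamped[j]),
        )
        for j, (a, b) in enumerate(pairs)
    ]


def _run_weighted(
    tree, aligned, method, pairs, states, alpha, alternative, include_stem, root_tie
):
    arr = tree.arrays()
    leaf_mat = aligned.loc[tree.leaf_names()].to_numpy(dtype=np.int8)
    col = {og: i for i, og in enumerate(aligned.columns)}
    node_states = None
    if method in ("asa", "asa_unweighted"):
        if states is not None:
            node_states = _override_states(tree, arr, aligned, states)
        else:
            masks, _ = parsimony.fitch_matrix(
                arr, aligned.loc[arr.leaf_ids].to_numpy(dtype=np.int8)
            )
            node_states = parsimony.acctran_matrix(arr, masks, root_tie=root_tie)

    results = []
    for a, b in pairs:
        ia, ib = col[a], col[b]
        if method == "naive":
            cells = weighted.naive_counts(leaf_mat[:, ia], leaf_mat[:, ib])
        elif method == "rle":
            cells = weighted.rle_counts(tree, leaf_mat[:, ia], leaf_mat[:, ib])
        elif method == "cwa":
            cells = weighted.cwa_counts(tree, leaf_mat[:, ia], leaf_mat[:, ib])
        else:
            cells = weighted.asa_counts(
                arr,
                node_states[:, ia],
                node_states[:, ib],
                weighted=(method == "asa"),
                include_stem=include_stem,
            )
        p, sign = weighted.contingency_test(*cells, alternative=alternative)
        results.append(
            PairResult(
                og1=a,
                og2=b,
                method=method,
                p_value=p,
                direction=_direction(sign, p, alpha),
                assoc=sign,
                c11=cells[0],
                c10=cells[1],
                c01=cells[2],
                c00=cells[3],
                n=int(sum(cells)) if method == "naive" else None,
            )
        )
    return results


def results_to_frame(results: list[PairResult], bh: bool = False) -> pd.DataFrame:
    """Tabulate pair results; optionally add a Benjamini-Hochberg column."""
    df = pd.DataFrame([vars(r) for r in results])
    if bh and len(df):
        m = len(df)
        order = np.argsort(df["p_value"].to_numpy(), kind="stable")
        adj = np.empty(m)
        ranked = df["p_value"].to_numpy()[order] * m / (np.arange(m) + 1)
        adj[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        df["p_adjusted"] = np.minimum(adj, 1.0)
    return df
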