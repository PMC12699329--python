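"""Rank-based evaluation of pair scores against truth labels.

Datasets of co-evolving pairs are extremely unbalanced (positives are a
percent or less of labelled pairs), so methods are compared by the area
under the precision-recall curve and by the number of true positives
recovered at fixed recall (TPR) thresholds.  Only labelled pairs enter the
ranking; ties are processed as one block so the curve does not depend on
input order, and the area uses the step-wise (interpolation-free) rule
sum over blocks of (recall_i - recall_{i-1}) * precision_i.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["pr_curve", "prauc", "positives_at_tpr", "score_results", "evaluate_methods"]


def _blocks(scores: np.ndarray, labels: np.ndarray):
    """Cumulative TP/FP after each tie block of descending score."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("no positive pairs in the ranking")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order].astype(np.int64)
    # last index of each tie block
    last = np.flatnonzero(np.append(s[1:] != s[:-1], True))
    tp = np.cumsum(y)[last]
    fp = np.cumsum(1 - y)[last]
    return tp, fp, n_pos


def pr_curve(scores, labels):
    """(recall, precision) points after each tie block, descending score."""
    tp, fp, n_pos = _blocks(scores, labels)
    recall = tp / n_pos
    precision = tp / (tp + fp)
    return recall, precision


def prauc(scores, labels) -> float:
    """Step-wise area under the precision-recall curve, in [0, 1]."""
    recall, precision = pr_curve(scores, labels)
    prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev) * precision))


def positives_at_tpr(scores, labels, tpr: float) -> int:
    """True positives at the loosest threshold whose recall is >= ``tpr``."""
    if not 0 < tpr <= 1:
        raise ValueError("tpr must be in (0, 1]")
    tp, _, n_pos = _blocks(scores, labels)
    recall = tp / n_pos
    idx = int(np.argmax(recall >= tpr))
    if recall[idx] < tpr:  # unreachable: recall ends at 1
        idx = len(recall) - 1
    return int(tp[idx])


def score_results(results: pd.DataFrame, include_negative: bool = False) -> pd.Series:
    """Ranking score from a pair-results frame: signed -log10 p.

    Pairs whose point association is co-occurrence rank by significance;
    contrapositive pairs rank at or below zero (strongly avoiding pairs
    last) unless ``include_negative`` ranks them by |association| too.
    """
    p = results["p_value"].to_numpy(dtype=float).clip(min=1e-300)
    sign = results["assoc"].to_numpy(dtype=float)
    logp = -np.log10(p)
    if include_negative:
        return pd.Series(logp, index=results.index)
    return pd.Series(np.where(sign > 0, logp, -logp * (sign < 0)), index=results.index)


def evaluate_methods(
    results_by_method: dict[str, pd.DataFrame],
    truth: pd.DataFrame,
    tprs=(0.9, 0.8, 0.7, 0.6, 0.5),
) -> pd.DataFrame:
    """PRAUC and positives-at-TPR summary per method.

    ``truth`` carries columns og1, og2, label; each results frame carries
    og1, og2, p_value, assoc.  Unlabelled pairs are ignored.
    """
    key = lambda df: list(zip(df["og1"], df["og2"]))
    labels = {frozenset(k): int(v) for k, v in zip(key(truth), truth["label"])}
    rows = []
    for method, res in results_by_method.items():
        mask = [frozenset(k) in labels for k in key(res)]
        sub = res.loc[mask].reset_index(drop=True)
        y = np.array([labels[frozenset(k)] for k in key(sub)])
        s = score_results(sub).to_numpy()
        row = {"method": method, "n_pairs": len(sub), "prauc": prauc(s, y)}
        for t in tprs:
            row[f"tp_at_tpr{t:g}"] = positives_at_tpr(s, y, t)
        rows.append(row)
    return pd.DataFrame(rows)
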