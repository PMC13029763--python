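"""Independent brute-force oracles used to cross-check module computations.

These deliberately avoid the implementation paths they verify: the AUC is a
pairwise rank comparison, average precision is an explicit step-wise sweep,
MCC/balanced accuracy come straight from the confusion-matrix formulas,
similarity is a double loop over bit sets, and sphere-exclusion clustering
is a literal restatement of the algorithm over python sets.
"""

from __future__ import annotations

import math

import numpy as np


def auc_pairwise(probs, labels) -> float:
    """ROC-AUC as the probability a positive outranks a negative (ties 0.5)."""
    probs = np.asarray(probs, float)
    labels = np.asarray(labels, int)
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def ap_stepwise(probs, labels) -> float:
    """Average precision via an explicit sweep over distinct thresholds."""
    probs = np.asarray(probs, float)
    labels = np.asarray(labels, int)
    n_pos = labels.sum()
    thresholds = np.unique(probs)[::-1]
    ap = 0.0
    prev_recall = 0.0
    for t in thresholds:
        pred = probs >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def confusion(probs, labels, threshold):
    probs = np.asarray(probs, float)
    labels = np.asarray(labels, int)
    pred = (probs >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    return tp, fp, fn, tn


def mcc_formula(probs, labels, threshold=0.5) -> float:
    tp, fp, fn, tn = confusion(probs, labels, threshold)
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def balanced_accuracy_formula(probs, labels, threshold=0.5) -> float:
    tp, fp, fn, tn = confusion(probs, labels, threshold)
    tpr = tp / (tp + fn) if tp + fn else 0.0
    tnr = tn / (tn + fp) if tn + fp else 0.0
    return (tpr + tnr) / 2.0


def threshold_sweep_max(probs, labels, metric=mcc_formula):
    """Best (threshold, score) over midpoint candidates plus 0 and 1.

    Ties go to the smallest candidate, mirroring the documented rule.
    """
    uniq = np.unique(np.asarray(probs, float))
    candidates = np.unique(np.concatenate(([0.0], (uniq[:-1] + uniq[1:]) / 2, [1.0])))
    best_thr, best = None, -np.inf
    for thr in candidates:
        score = metric(probs, labels, thr)
        if score > best:
            best, best_thr = score, float(thr)
    return best_thr, best


def tanimoto_loops(a, b) -> float:
    """Tanimoto by explicit element loop over two 0/1 vectors."""
    inter = union = 0
    for x, y in zip(a, b):
        if x and y:
            inter += 1
        if x or y:
            union += 1
    return inter / union if union else 0.0


def sphere_exclusion(fps, scores, ids, cutoff):
    """Literal sphere-exclusion clustering over python sets.

    Recomputes each candidate's unassigned-neighbor count every iteration;
    ties break on higher score, then smaller id. Returns a list of
    (centroid_id, sorted member id list) tuples.
    """
    n = len(fps)
    dist = [[1.0 - tanimoto_loops(fps[i], fps[j]) for j in range(n)] for i in range(n)]
    unassigned = set(range(n))
    clusters = []
    while unassigned:
        best, best_key = None, None
        for i in sorted(unassigned):
            neigh = {j for j in unassigned if j != i and dist[i][j] <= cutoff}
            key = (-len(neigh), -scores[i], ids[i])
            if best is None or key < best_key:
                best, best_key = i, key
        members = {best} | {j for j in unassigned if j != best and dist[best][j] <= cutoff}
        clusters.append((ids[best], sorted(ids[j] for j in members)))
        unassigned -= members
    return clusters
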