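"""Independent brute-force oracles used across the test suite.

Each oracle recomputes a quantity by direct enumeration, staying independent
of the library code paths it checks.
"""

from __future__ import annotations

import numpy as np


def pair_counting_auc(labels, probs) -> float:
    """AUC as P(p_active > p_inactive) + 0.5 * P(tie), by full enumeration."""
    labels = np.asarray(labels)
    probs = np.asarray(probs, dtype=float)
    act = probs[labels == 1]
    inact = probs[labels == 0]
    wins = ties = 0.0
    for a in act:
        for b in inact:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(act) * len(inact))


def exhaustive_optimal_threshold(labels, probs):
    """Minimize d = sqrt((1-TPR)^2 + FPR^2) over all unique-probability
    cutoffs plus a sentinel above the maximum (inclusive >= calls).

    Ties break toward higher TPR, then lower threshold.  Returns
    (threshold, d, tpr, fpr).
    """
    import math

    labels = np.asarray(labels)
    probs = np.asarray(probs, dtype=float)
    P = int((labels == 1).sum())
    N = int((labels == 0).sum())
    candidates = sorted(set(probs.tolist()))
    candidates.append(np.nextafter(probs.max(), np.inf))
    best = None
    for t in candidates:
        preds = probs >= t
        tp = int((preds & (labels == 1)).sum())
        fp = int((preds & (labels == 0)).sum())
        fn = P - tp
        # exact integer squared distance scaled by (P*N)^2; ties resolve
        # toward higher TPR then lower threshold
        key = ((fn * N) ** 2 + (fp * P) ** 2, -tp, t)
        if best is None or key < best[0]:
            best = (key, t, tp, fp)
    key, t, tp, fp = best
    d = math.sqrt(key[0]) / (P * N)
    return t, d, tp / P, fp / N


def greedy_maxmin(fps, k: int, first: int) -> list[int]:
    """Exhaustive greedy MaxMin on Tanimoto distance, recomputing every
    pairwise distance at every step; ties broken toward the lowest index."""
    fps = [np.asarray(f, dtype=bool) for f in fps]

    def dist(a, b):
        inter = np.sum(a & b)
        union = np.sum(a | b)
        if union == 0:
            return 0.0
        return 1.0 - inter / union

    selected = [first]
    while len(selected) < k:
        best_idx, best_min = None, -1.0
        for i in range(len(fps)):
            if i in selected:
                continue
            dmin = min(dist(fps[i], fps[j]) for j in selected)
            if dmin > best_min:
                best_idx, best_min = i, dmin
        selected.append(best_idx)
    return selected


def tally_confusion(labels, preds):
    """Direct loop tally of the 2x2 confusion matrix."""
    tp = fp = tn = fn = 0
    for y, p in zip(labels, preds):
        if y == 1 and p == 1:
            tp += 1
        elif y == 0 and p == 1:
            fp += 1
        elif y == 0 and p == 0:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def random_roc_instance(rng, n_max=50, allow_ties=True):
    """Random (labels, probs) with both classes present and optional ties."""
    n = int(rng.integers(4, n_max + 1))
    labels = rng.integers(0, 2, size=n)
    while len(np.unique(labels)) < 2:
        labels = rng.integers(0, 2, size=n)
    if allow_ties and rng.random() < 0.5:
        # coarse grid forces tied probabilities
        probs = rng.integers(0, 6, size=n) / 5.0
    else:
        probs = rng.random(n)
    return labels, probs
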