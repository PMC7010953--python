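"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorised code paths: mutual
information is an exhaustive sum over the joint count table, and the mRMR
oracle re-evaluates the full relevance-minus-mean-redundancy objective over
every remaining candidate at every step.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def mi_oracle(x, y) -> float:
    """Plug-in MI in bits by exhaustive summation over joint counts."""
    x = list(x)
    y = list(y)
    n = len(x)
    cxy = Counter(zip(x, y))
    cx = Counter(x)
    cy = Counter(y)
    total = 0.0
    for (a, b), c in cxy.items():
        pxy = c / n
        total += pxy * math.log2(pxy / ((cx[a] / n) * (cy[b] / n)))
    return max(total, 0.0)


def mrmr_oracle(states: np.ndarray, labels: np.ndarray, top_n: int) -> list[int]:
    """Greedy mRMR by full re-evaluation each step; ties -> lowest index.

    Scores within 1e-10 of the step maximum count as tied (exact duplicates
    produce mathematically equal scores that differ only in round-off), and
    the lowest gene index wins. Returns the selected gene indices in rank
    order.
    """
    G = states.shape[0]
    relevance = [mi_oracle(states[g], labels) for g in range(G)]
    selected: list[int] = []
    remaining = list(range(G))
    while remaining and len(selected) < top_n:
        scores = {}
        for j in remaining:
            if selected:
                red = sum(mi_oracle(states[j], states[i]) for i in selected)
                red /= len(selected)
            else:
                red = 0.0
            scores[j] = relevance[j] - red
        mx = max(scores.values())
        best_j = next(j for j in remaining if scores[j] >= mx - 1e-10)
        selected.append(best_j)
        remaining.remove(best_j)
    return selected


def loocv_naive(spec, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Literal per-fold retraining via the public single-fold adapter."""
    from mrmr_ifs.classifiers import fit_predict

    n = len(y)
    preds = np.empty(n, dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        preds[i] = fit_predict(spec, X[mask], y[mask], X[i : i + 1])[0]
    return preds
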