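"""Independent brute-force reference implementations used only by tests."""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.stats import rankdata


def signed_rank_p_bruteforce(diffs: np.ndarray, zero_method: str = "discard") -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    nonzero = d != 0
    if not nonzero.any():
        return 1.0
    if zero_method == "discard":
        ranks = rankdata(np.abs(d[nonzero]))
    else:
        ranks = rankdata(np.abs(d))[nonzero]
    d = d[nonzero]
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = np.array([np.sum(ranks[np.array(signs, dtype=bool)])
                   for signs in product([0, 1], repeat=n)])
    lo = np.mean(ws <= w_obs + 1e-9)
    hi = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(lo, hi))


def bh_adjust_quadratic(p: np.ndarray) -> np.ndarray:
    """Quadratic-time Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    adj = np.empty(m)
    for i in range(m):
        # adjusted p_i = min over thresholds t >= p_i of t * m / rank(t)
        best = np.inf
        for j in range(m):
            if p[j] >= p[i] - 1e-15:
                rank = np.sum(p <= p[j] + 1e-15)
                best = min(best, p[j] * m / rank)
        adj[i] = min(1.0, best)
    return adj


def auc_concordance(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the pairwise concordance probability U/(n1*n0), ties counted 1/2."""
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    cases = s[lab == "case"]
    controls = s[lab == "control"]
    wins = 0.0
    for c in cases:
        for k in controls:
            if c > k:
                wins += 1.0
            elif c == k:
                wins += 0.5
    return wins / (len(cases) * len(controls))


def average_linkage_bruteforce(dist: np.ndarray) -> list[float]:
    """Merge heights of naive O(n^3) average-linkage clustering (UPGMA)."""
    n = dist.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    heights = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return heights
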