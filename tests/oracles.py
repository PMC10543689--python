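"""Independent reference implementations used only to check the package.

Each oracle computes its quantity by a different route from the library:
Ward merge costs come from the closed-form generalized-centroid identity
rather than the Lance-Williams recurrence, silhouettes from literal
per-point loops, hypergeometric tails from exact combinatorial
enumeration, Welch statistics from the textbook formula, and BH from the
step-up definition applied by hand.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def ward_bruteforce(d: np.ndarray) -> np.ndarray:
    """O(N^3) Ward agglomerator from first principles.

    The generalized Ward cost between clusters A and B is
        D2(A,B) = 2 n_A n_B / (n_A + n_B) * ||c_A - c_B||^2
    with the centroid gap expanded purely in pairwise squared
    dissimilarities:
        ||c_A - c_B||^2 = T_AB/(n_A n_B) - T_AA/(2 n_A^2) - T_BB/(2 n_B^2)
    (T_XY sums d^2 over ordered pairs). Ties pick the first minimal slot
    pair in scan order, matching the library's convention.
    """
    n = d.shape[0]
    d2 = d.astype(float) ** 2

    def t_sum(a: list[int], b: list[int]) -> float:
        return float(d2[np.ix_(a, b)].sum())

    def cost(a: list[int], b: list[int]) -> float:
        na, nb = len(a), len(b)
        gap = t_sum(a, b) / (na * nb) - t_sum(a, a) / (2 * na**2) - t_sum(b, b) / (2 * nb**2)
        return 2.0 * na * nb / (na + nb) * gap

    slots: dict[int, list[int]] = {i: [i] for i in range(n)}
    node_id = {i: i for i in range(n)}
    merges = np.zeros((n - 1, 4))
    for step in range(n - 1):
        best = None
        keys = sorted(slots)
        for ii, i in enumerate(keys):
            for j in keys[ii + 1 :]:
                c = cost(slots[i], slots[j])
                if best is None or c < best[0] - 1e-12:
                    best = (c, i, j)
        c, i, j = best
        a, b = sorted((node_id[i], node_id[j]))
        merges[step] = (a, b, math.sqrt(max(c, 0.0)), len(slots[i]) + len(slots[j]))
        slots[i] = slots[i] + slots[j]
        del slots[j]
        node_id[i] = n + step
    return merges


def silhouette_direct(d: np.ndarray, labels) -> np.ndarray:
    """Literal per-point silhouette evaluation."""
    labels = np.asarray(labels)
    n = len(labels)
    out = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            out[i] = 0.0
            continue
        a = d[i, own & (np.arange(n) != i)].mean()
        b = min(
            d[i, labels == c].mean() for c in np.unique(labels) if c != labels[i]
        )
        out[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return out


def hypergeom_tail_exact(k: int, big_n: int, term: int, draw: int) -> float:
    """P(X >= k) for X ~ Hypergeom(big_n, term, draw) by full enumeration."""
    total = 0
    for x in range(k, min(term, draw) + 1):
        total += math.comb(term, x) * math.comb(big_n - term, draw - x)
    return total / math.comb(big_n, draw)


def welch_manual(a, b) -> tuple[float, float]:
    """Welch two-sample t from the textbook formula with the
    Welch-Satterthwaite degrees of freedom."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


def bh_manual(ps) -> np.ndarray:
    """Benjamini-Hochberg step-up by definition."""
    ps = np.asarray(ps, float)
    m = len(ps)
    order = np.argsort(ps)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, ps[idx] * m / rank)
        adj[idx] = running
    return adj
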