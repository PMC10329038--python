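"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a different algorithm (enumeration,
graph search, direct summation, permutation) than the production code
path it checks, so agreement is evidence of correctness rather than
self-consistency.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import networkx as nx
import numpy as np


def kleinberg_cost(levels, gaps, lambda_bar, s, gamma) -> float:
    """Cost of one level sequence under the burst automaton (start at 0)."""
    n = len(gaps)
    cost = 0.0
    prev = 0
    for lv, x in zip(levels, gaps):
        if lv > prev:
            cost += gamma * (lv - prev) * math.log(n)
        lam = lambda_bar * s**lv
        cost += -(math.log(lam) - lam * x)
        prev = lv
    return cost


def kleinberg_enumerate(gaps, lambda_bar, s, gamma, max_level):
    """Exhaustive minimization over all level sequences (tiny n only)."""
    n = len(gaps)
    best_cost, best_seq, n_opt = math.inf, None, 0
    for seq in itertools.product(range(max_level + 1), repeat=n):
        c = kleinberg_cost(seq, gaps, lambda_bar, s, gamma)
        if c < best_cost - 1e-12:
            best_cost, best_seq, n_opt = c, seq, 1
        elif abs(c - best_cost) <= 1e-12:
            n_opt += 1
    return best_cost, best_seq, n_opt


def kleinberg_shortest_path(gaps, lambda_bar, s, gamma, max_level):
    """Optimal automaton cost as a shortest path on the trellis graph."""
    n = len(gaps)
    L = max_level + 1
    trans = gamma * math.log(n)
    G = nx.DiGraph()
    for j in range(L):
        lam = lambda_bar * s**j
        emit = -(math.log(lam) - lam * gaps[0])
        up = trans * max(j - 0, 0)
        G.add_edge("src", (0, j), weight=up + emit)
    for t in range(n - 1):
        for j in range(L):
            for i in range(L):
                lam = lambda_bar * s**i
                emit = -(math.log(lam) - lam * gaps[t + 1])
                up = trans * max(i - j, 0)
                G.add_edge((t, j), (t + 1, i), weight=up + emit)
    for j in range(L):
        G.add_edge((n - 1, j), "dst", weight=0.0)
    # emission costs may be negative (density > 1), so Bellman-Ford
    length, path = nx.single_source_bellman_ford(G, "src", "dst")
    seq = [node[1] for node in path[1:-1]]
    return length, seq


def te_direct(source, target, base: float = 2.0) -> float:
    """Transfer entropy source→target (k = l = 1) by direct summation
    over observed triples, using plain dict counting."""
    x = list(map(int, target))
    y = list(map(int, source))
    n = len(x) - 1
    c_xyz: Counter = Counter()
    c_xy: Counter = Counter()
    c_xx: Counter = Counter()
    c_x: Counter = Counter()
    for t in range(n):
        c_xyz[(x[t + 1], x[t], y[t])] += 1
        c_xy[(x[t], y[t])] += 1
        c_xx[(x[t + 1], x[t])] += 1
        c_x[x[t]] += 1
    te = 0.0
    for (x1, x0, y0), c in c_xyz.items():
        p = c / n
        cond_full = c / c_xy[(x0, y0)]
        cond_marg = c_xx[(x1, x0)] / c_x[x0]
        te += p * math.log(cond_full / cond_marg, base)
    return te


def bm_statistic(a: np.ndarray, b: np.ndarray):
    """Scalar Brunner–Munzel statistic (independent scalar reimplementation)."""
    from scipy.stats import rankdata

    n1, n2 = len(a), len(b)
    R = rankdata(np.concatenate((a, b)))
    Ra, Rb = R[:n1], R[n1:]
    Sa2 = np.sum((Ra - rankdata(a) - Ra.mean() + (n1 + 1) / 2) ** 2) / (n1 - 1)
    Sb2 = np.sum((Rb - rankdata(b) - Rb.mean() + (n2 + 1) / 2) ** 2) / (n2 - 1)
    se = (n1 + n2) * np.sqrt(Sa2 / (n1 * n2**2) + Sb2 / (n2 * n1**2))
    return (Rb.mean() - Ra.mean()) / se


def bm_combination_masks(n: int, k: int) -> np.ndarray:
    """Boolean matrix of all C(n, k) group-A membership masks."""
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), k)),
        dtype=np.int64,
    ).reshape(-1, k)
    masks = np.zeros((combos.shape[0], n), dtype=bool)
    np.put_along_axis(masks, combos, True, axis=1)
    return masks


def bm_permutation_p(pooled: np.ndarray, n1: int, masks: np.ndarray) -> float:
    """Exact two-sided permutation p of the BM statistic over all splits.

    ``pooled`` holds group A first (n1 values, tie-free), ``masks`` comes
    from :func:`bm_combination_masks`.  Fully vectorized.
    """
    n = pooled.size
    n2 = n - n1
    order = np.argsort(pooled)
    M = masks[:, order].astype(np.float64)  # group A membership in rank order
    pos = np.arange(1, n + 1, dtype=np.float64)
    R_a_mean = (M * pos).sum(axis=1) / n1
    R_b_mean = ((1 - M) * pos).sum(axis=1) / n2
    cumA = np.cumsum(M, axis=1)
    cumB = np.cumsum(1 - M, axis=1)
    DA = pos[None, :] - cumA - R_a_mean[:, None] + (n1 + 1) / 2
    DB = pos[None, :] - cumB - R_b_mean[:, None] + (n2 + 1) / 2
    Sa2 = (DA**2 * M).sum(axis=1) / (n1 - 1)
    Sb2 = (DB**2 * (1 - M)).sum(axis=1) / (n2 - 1)
    se = (n1 + n2) * np.sqrt(Sa2 / (n1 * n2**2) + Sb2 / (n2 * n1**2))
    with np.errstate(divide="ignore"):
        W = (R_b_mean - R_a_mean) / se  # extreme splits: se=0 -> |W|=inf
    w_obs = bm_statistic(pooled[:n1], pooled[n1:])
    return float(np.mean(np.abs(W) >= abs(w_obs) - 1e-12))
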