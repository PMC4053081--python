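"""Independent brute-force oracles used to check the package's primitives.

Everything here is written as directly from the defining formulas as
possible (explicit loops, enumeration, 1-D numeric maximization) and shares
no code with the implementations under test.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np
from scipy.optimize import minimize_scalar


def breslow_loglik_naive(beta, X, time, event) -> float:
    """Breslow log partial likelihood by explicit risk-set loops."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(time):
        X = X.T
    beta = np.atleast_1d(np.asarray(beta, float))
    ll = 0.0
    for i in range(len(time)):
        if event[i] != 1:
            continue
        risk = [j for j in range(len(time)) if time[j] >= time[i]]
        denom = sum(math.exp(float(X[j] @ beta)) for j in risk)
        ll += float(X[i] @ beta) - math.log(denom)
    return ll


def cox_beta_1d_oracle(x, time, event, bound: float = 10.0) -> float:
    """Single-covariate Breslow MLE by bounded 1-D numeric maximization."""
    res = minimize_scalar(
        lambda b: -breslow_loglik_naive([b], np.asarray(x)[:, None], time, event),
        bounds=(-bound, bound),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def bh_naive(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up from the textbook definition, with loops."""
    p = list(map(float, pvalues))
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    running_min = 1.0
    for rank_pos in range(n - 1, -1, -1):
        i = order[rank_pos]
        running_min = min(running_min, n * p[i] / (rank_pos + 1))
        adj[i] = min(running_min, 1.0)
    return np.array(adj)


def k_ball_naive(edges, seed, k) -> set:
    """Nodes within distance k of seed, by a hand-rolled BFS over an edge list."""
    adj: dict = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    dist = {seed: 0}
    queue = deque([seed])
    while queue:
        node = queue.popleft()
        if dist[node] == k:
            continue
        for nb in adj.get(node, ()):
            if nb not in dist:
                dist[nb] = dist[node] + 1
                queue.append(nb)
    return set(dist)


def hypergeom_tail_naive(M: int, K: int, N: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(M, K, N), by direct enumeration."""
    total = math.comb(M, N)
    acc = 0
    for j in range(k, min(K, N) + 1):
        if N - j <= M - K:
            acc += math.comb(K, j) * math.comb(M - K, N - j)
    return acc / total


def merge_naive(gene_sets) -> list:
    """Shared-gene merging by explicit union-find."""
    n = len(gene_sets)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if set(gene_sets[i]) & set(gene_sets[j]):
                parent[find(i)] = find(j)
    groups: dict = {}
    for i in range(n):
        groups.setdefault(find(i), set()).update(gene_sets[i])
    return sorted(frozenset(g) for g in groups.values())
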