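"""Brute-force reference implementations for small graphs.

Deliberately naive and independent of the package's computation paths:
explicit Floyd-Warshall relaxation, exhaustive triangle / subgraph
enumeration, and shortest-path counting from the distance matrix. Only
usable for graphs of a dozen nodes or so.
"""

from __future__ import annotations

import itertools

import numpy as np


def floyd_warshall(W: np.ndarray, weighted: bool) -> np.ndarray:
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and W[i, j] > 0:
                D[i, j] = 1.0 / W[i, j] if weighted else 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def global_efficiency(W: np.ndarray, weighted: bool) -> float:
    n = W.shape[0]
    if n < 2:
        return 0.0
    D = floyd_warshall(W, weighted)
    s = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(D[i, j]) and D[i, j] > 0:
                s += 1.0 / D[i, j]
    return s / (n * (n - 1))


def char_path_length(W: np.ndarray, weighted: bool) -> float:
    n = W.shape[0]
    D = floyd_warshall(W, weighted)
    vals = [D[i, j] for i in range(n) for j in range(n) if i != j]
    if not vals or not np.isfinite(vals).all():
        return float("inf")
    return float(np.mean(vals))


def local_efficiency(W: np.ndarray, weighted: bool) -> float:
    n = W.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        total += global_efficiency(sub, weighted)
    return total / n if n else 0.0


def clustering_and_transitivity(W: np.ndarray) -> tuple[float, float]:
    """Binary triangle enumeration."""
    A = (W > 0).astype(int)
    n = A.shape[0]
    tri = np.zeros(n)
    triples = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if A[i, j]]
        k = len(nbrs)
        triples[i] = k * (k - 1) / 2
        for a, b in itertools.combinations(nbrs, 2):
            if A[a, b]:
                tri[i] += 1
    cc = [tri[i] / triples[i] if triples[i] > 0 else 0.0 for i in range(n)]
    clustering = float(np.mean(cc)) if n else 0.0
    transitivity = (float(tri.sum() / triples.sum())
                    if triples.sum() > 0 else 0.0)
    return clustering, transitivity


def weighted_clustering(W: np.ndarray) -> float:
    """Onnela geometric-mean triangle clustering, enumerated."""
    n = W.shape[0]
    wmax = W.max() if W.max() > 0 else 1.0
    Wn = W / wmax
    vals = []
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        s = 0.0
        for a, b in itertools.combinations(nbrs, 2):
            if W[a, b] > 0:
                s += (Wn[i, a] * Wn[i, b] * Wn[a, b]) ** (1.0 / 3.0)
        vals.append(2.0 * s / (k * (k - 1)))
    return float(np.mean(vals)) if n else 0.0


def mean_betweenness(W: np.ndarray, weighted: bool) -> float:
    """Fractional shortest-path counting from the distance matrix."""
    n = W.shape[0]
    D = floyd_warshall(W, weighted)
    length = np.where(W > 0, 1.0 / W if weighted else 1.0, np.inf)

    sigma = np.zeros((n, n))

    def count_paths(s, t, memo):
        if s == t:
            return 1.0
        if (s, t) in memo:
            return memo[(s, t)]
        total = 0.0
        for p in range(n):
            if p != t and np.isfinite(length[p, t]) and \
                    abs(D[s, p] + length[p, t] - D[s, t]) < 1e-9:
                total += count_paths(s, p, memo)
        memo[(s, t)] = total
        return total

    memos = [dict() for _ in range(n)]
    for s in range(n):
        for t in range(n):
            if s != t and np.isfinite(D[s, t]):
                sigma[s, t] = count_paths(s, t, memos[s])

    bc = np.zeros(n)
    for v in range(n):
        for s in range(n):
            for t in range(s + 1, n):
                if v in (s, t) or not np.isfinite(D[s, t]) \
                        or sigma[s, t] == 0:
                    continue
                if abs(D[s, v] + D[v, t] - D[s, t]) < 1e-9:
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return float(bc.mean())


def rich_club_mean(W: np.ndarray) -> float:
    A = (W > 0).astype(int)
    deg = A.sum(axis=1)
    phis = []
    for k in range(1, int(deg.max()) + 1 if deg.size else 1):
        nodes = [i for i in range(len(deg)) if deg[i] > k]
        if len(nodes) < 2:
            continue
        e = sum(A[a, b] for a, b in itertools.combinations(nodes, 2))
        phis.append(2.0 * e / (len(nodes) * (len(nodes) - 1)))
    return float(np.mean(phis)) if phis else 0.0


def modularity_of_partition(W: np.ndarray, parts: list[set[int]],
                            weighted: bool) -> float:
    M = W if weighted else (W > 0).astype(float)
    two_m = M.sum()
    if two_m == 0:
        return 0.0
    q = 0.0
    for c in parts:
        nodes = sorted(c)
        e_c = M[np.ix_(nodes, nodes)].sum()          # 2x intra-weight
        d_c = M[nodes, :].sum()
        q += e_c / two_m - (d_c / two_m) ** 2
    return q


def best_two_way_spectral_modularity(W: np.ndarray, weighted: bool) -> float:
    """Q of the leading-eigenvector two-community split."""
    M = W if weighted else (W > 0).astype(float)
    k = M.sum(axis=1)
    two_m = M.sum()
    if two_m == 0:
        return 0.0
    B = M - np.outer(k, k) / two_m
    evals, evecs = np.linalg.eigh(B)
    v = evecs[:, np.argmax(evals)]
    part_a = set(np.flatnonzero(v >= 0).tolist())
    part_b = set(range(len(k))) - part_a
    parts = [p for p in (part_a, part_b) if p]
    return modularity_of_partition(W, parts, weighted)


def random_graph(rng: np.random.Generator, n: int, p: float,
                 weighted: bool) -> np.ndarray:
    A = np.triu((rng.random((n, n)) < p).astype(float), 1)
    if weighted:
        A *= rng.uniform(0.2, 2.0, size=(n, n))
    return A + A.T
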