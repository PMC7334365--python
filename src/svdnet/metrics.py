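"""Graph-theoretic network measures for weighted and binarized connectomes.

Implements the 21-measure vector used throughout the pipeline: nine binary
measures (density, mean degree, global/local efficiency, characteristic path
length, clustering, transitivity, modularity, betweenness), eight weighted
counterparts (mean strength instead of density/degree), two topology measures
(degree assortativity, rich-club coefficient), and the two null-normalized
efficiencies (observed weighted efficiency divided by the mean over a
degree-preserving null ensemble).

Conventions
-----------
* Networks are symmetric nonnegative matrices with zero diagonal.
* Weighted shortest-path distance on an edge is ``1/w`` by default (the
  standard convention for FA-weighted structural connectomes); an alternative
  ``-log(w/w_max)`` mapping is available via ``distance="neglog"``.
* Unreachable node pairs contribute zero to efficiency; characteristic path
  length returns ``inf`` when any pair is unreachable, and callers record the
  subject as having disconnected nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "METRIC_NAMES",
    "NullEnsemble",
    "global_efficiency",
    "local_efficiency",
    "char_path_length",
    "clustering_transitivity",
    "modularity",
    "mean_betweenness",
    "assortativity",
    "rich_club",
    "degree_preserving_nulls",
    "normalized_efficiencies",
    "compute_all",
]

#: Canonical ordering of the 21-measure vector.
METRIC_NAMES = (
    "density",
    "mean_degree",
    "global_efficiency_b",
    "local_efficiency_b",
    "char_path_length_b",
    "clustering_b",
    "transitivity_b",
    "modularity_b",
    "betweenness_b",
    "mean_strength",
    "global_efficiency_w",
    "local_efficiency_w",
    "char_path_length_w",
    "clustering_w",
    "transitivity_w",
    "modularity_w",
    "betweenness_w",
    "assortativity",
    "rich_club",
    "norm_global_efficiency",
    "norm_local_efficiency",
)


def _as_matrix(network) -> np.ndarray:
    """Accept a Connectome/BinaryConnectome-like object or a plain array."""
    if hasattr(network, "weights"):
        return np.asarray(network.weights, dtype=float)
    if hasattr(network, "adjacency"):
        return np.asarray(network.adjacency, dtype=float)
    return np.asarray(network, dtype=float)


def _validate(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("network matrix must be square")
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("network matrix must be symmetric")
    if (W < 0).any():
        raise ValueError("network weights must be nonnegative")
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    return W


def _length_matrix(W: np.ndarray, distance: str = "inverse") -> np.ndarray:
    """Map weights to edge lengths for shortest-path computation."""
    L = np.zeros_like(W)
    pos = W > 0
    if distance == "inverse":
        L[pos] = 1.0 / W[pos]
    elif distance == "neglog":
        wmax = W[pos].max() if pos.any() else 1.0
        # strictly positive lengths; the maximal edge gets a tiny epsilon
        L[pos] = -np.log(W[pos] / wmax) + 1e-12
    else:
        raise ValueError(f"unknown distance convention {distance!r}")
    return L


def distance_matrix(W, weighted: bool, distance: str = "inverse") -> np.ndarray:
    """All-pairs shortest-path distances (hop counts if ``weighted=False``)."""
    W = _validate(_as_matrix(W))
    if W.shape[0] == 0:
        return np.zeros((0, 0))
    if weighted:
        graph = csr_matrix(_length_matrix(W, distance))
        return shortest_path(graph, method="D", directed=False)
    graph = csr_matrix((W > 0).astype(np.int8))
    return shortest_path(graph, method="D", directed=False, unweighted=True)


def _efficiency_from_distances(D: np.ndarray) -> float:
    n = D.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(network, weighted: bool | None = None,
                      distance: str = "inverse") -> float:
    """Mean inverse shortest-path distance; unreachable pairs contribute 0."""
    W = _as_matrix(network)
    if weighted is None:
        weighted = not _is_binary(W)
    return _efficiency_from_distances(distance_matrix(W, weighted, distance))


def char_path_length(network, weighted: bool | None = None,
                     distance: str = "inverse") -> float:
    """Mean shortest-path distance over all pairs; ``inf`` if disconnected."""
    W = _as_matrix(network)
    if weighted is None:
        weighted = not _is_binary(W)
    D = distance_matrix(W, weighted, distance)
    n = D.shape[0]
    if n < 2:
        return float("inf")
    off = D[~np.eye(n, dtype=bool)]
    if not np.isfinite(off).all():
        return float("inf")
    return float(off.mean())


@njit(cache=True)
def _local_efficiency_kernel(L: np.ndarray) -> float:
    """Sum over nodes of neighbour-subgraph efficiency (Floyd–Warshall).

    ``L`` is the edge-length matrix (0 = no edge); neighbourhood membership
    is ``L > 0``.
    """
    n = L.shape[0]
    inf = np.inf
    total = 0.0
    idx = np.empty(n, dtype=np.int64)
    for i in range(n):
        m = 0
        for j in range(n):
            if L[i, j] > 0.0:
                idx[m] = j
                m += 1
        if m < 2:
            continue
        D = np.full((m, m), inf)
        for a in range(m):
            D[a, a] = 0.0
            for b in range(m):
                if a != b and L[idx[a], idx[b]] > 0.0:
                    D[a, b] = L[idx[a], idx[b]]
        for k in range(m):
            for a in range(m):
                dak = D[a, k]
                if dak == inf:
                    continue
                for b in range(m):
                    alt = dak + D[k, b]
                    if alt < D[a, b]:
                        D[a, b] = alt
        s = 0.0
        for a in range(m):
            for b in range(m):
                if a != b and D[a, b] < inf:
                    s += 1.0 / D[a, b]
        total += s / (m * (m - 1))
    return total


def local_efficiency(network, weighted: bool | None = None,
                     distance: str = "inverse") -> float:
    """Mean over nodes of the global efficiency of the neighbour subgraph.

    Nodes with fewer than two neighbours contribute zero. For the weighted
    variant the neighbour subgraph retains its weights and distances are
    ``1/w`` along subgraph edges (Latora–Marchiori generalization).
    """
    W = _validate(_as_matrix(network))
    if weighted is None:
        weighted = not _is_binary(W)
    n = W.shape[0]
    if n == 0:
        return 0.0
    if weighted:
        L = _length_matrix(W, distance)
    else:
        L = (W > 0).astype(float)
    return _local_efficiency_kernel(L) / n


def _is_binary(W: np.ndarray) -> bool:
    return bool(np.isin(np.unique(W), (0.0, 1.0)).all())


def _to_graph(W: np.ndarray, weighted: bool) -> nx.Graph:
    G = nx.Graph()
    n = W.shape[0]
    G.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(W, 1))
    if weighted:
        G.add_weighted_edges_from(
            (int(i), int(j), float(W[i, j])) for i, j in zip(ii, jj))
    else:
        G.add_edges_from((int(i), int(j)) for i, j in zip(ii, jj))
    return G


def clustering_transitivity(network, weighted: bool | None = None
                            ) -> tuple[float, float]:
    """(mean clustering coefficient, global transitivity).

    Binary: triangle-based definitions. Weighted: clustering uses the
    geometric mean of triangle weights (weights scaled by the maximum);
    transitivity is the weighted triangle intensity summed over nodes divided
    by the number of connected triples.
    """
    W = _validate(_as_matrix(network))
    if weighted is None:
        weighted = not _is_binary(W)
    A = (W > 0).astype(float)
    if not weighted:
        G = _to_graph(A, weighted=False)
        if G.number_of_nodes() == 0:
            return 0.0, 0.0
        return float(nx.average_clustering(G)), float(nx.transitivity(G))
    G = _to_graph(W, weighted=True)
    if G.number_of_nodes() == 0:
        return 0.0, 0.0
    clust = float(nx.average_clustering(G, weight="weight"))
    wmax = W.max()
    if wmax == 0:
        return 0.0, 0.0
    Wn = np.cbrt(W / wmax)
    tri = np.diagonal(Wn @ Wn @ Wn)  # 2 * weighted triangle count per node
    deg = A.sum(axis=1)
    denom = (deg * (deg - 1)).sum()
    trans = float(tri.sum() / denom) if denom > 0 else 0.0
    return clust, trans


def _modularity_q(M: np.ndarray, labels: np.ndarray) -> float:
    two_m = M.sum()
    if two_m == 0:
        return 0.0
    q = 0.0
    for c in np.unique(labels):
        nodes = labels == c
        q += M[np.ix_(nodes, nodes)].sum() / two_m \
            - (M[nodes].sum() / two_m) ** 2
    return float(q)


def _refine_partition(M: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Greedy single-node moves until no move improves Q."""
    labels = labels.copy()
    two_m = M.sum()
    if two_m == 0:
        return labels
    strength = M.sum(axis=1)
    for _ in range(50):
        improved = False
        for i in range(len(labels)):
            cur = labels[i]
            comms = np.unique(labels[M[i] > 0])
            best_gain, best_c = 0.0, cur
            for c in comms:
                if c == cur:
                    continue
                # gain of moving i from cur to c
                k_in_c = M[i, labels == c].sum()
                k_in_cur = M[i, labels == cur].sum()
                s_c = strength[labels == c].sum()
                s_cur = strength[labels == cur].sum() - strength[i]
                gain = (k_in_c - k_in_cur) / (two_m / 2.0) \
                    - strength[i] * (s_c - s_cur) / (2.0 * (two_m / 2.0) ** 2)
                if gain > best_gain + 1e-12:
                    best_gain, best_c = gain, c
            if best_c != cur:
                labels[i] = best_c
                improved = True
        if not improved:
            break
    return labels


def modularity(network, weighted: bool | None = None, seed: int = 0) -> float:
    """Maximized Newman modularity Q.

    Takes the best of three deterministic starts — CNM greedy agglomeration,
    seeded Louvain, and a leading-eigenvector two-way split — each polished
    by a local node-moving refinement.
    """
    W = _validate(_as_matrix(network))
    if weighted is None:
        weighted = not _is_binary(W)
    M = W if weighted else (W > 0).astype(float)
    if M.sum() == 0:
        return 0.0
    G = _to_graph(M, weighted=True)
    n = M.shape[0]

    candidates: list[np.ndarray] = []
    for comms in (
        nx.community.greedy_modularity_communities(G, weight="weight"),
        nx.community.louvain_communities(G, weight="weight", seed=seed),
    ):
        labels = np.empty(n, dtype=int)
        for c, nodes in enumerate(comms):
            labels[list(nodes)] = c
        candidates.append(labels)
    # leading-eigenvector bisection of the modularity matrix
    k = M.sum(axis=1)
    B = M - np.outer(k, k) / M.sum()
    evals, evecs = np.linalg.eigh(B)
    v = evecs[:, np.argmax(evals)]
    candidates.append((v >= 0).astype(int))

    best = max(_modularity_q(M, _refine_partition(M, lab))
               for lab in candidates)
    return float(max(best, 0.0))


def mean_betweenness(network, weighted: bool | None = None,
                     distance: str = "inverse") -> float:
    """Mean node betweenness (unordered pairs, fractional over tied paths)."""
    W = _validate(_as_matrix(network))
    if weighted is None:
        weighted = not _is_binary(W)
    n = W.shape[0]
    if n == 0:
        return 0.0
    if weighted:
        L = _length_matrix(W, distance)
        G = _to_graph(L, weighted=True)
        bc = nx.betweenness_centrality(G, normalized=False, weight="weight")
    else:
        G = _to_graph((W > 0).astype(float), weighted=False)
        bc = nx.betweenness_centrality(G, normalized=False)
    return float(np.mean(list(bc.values())))


def assortativity(network) -> float:
    """Degree assortativity of the binarized topology (0 if undefined)."""
    W = _validate(_as_matrix(network))
    G = _to_graph((W > 0).astype(float), weighted=False)
    if G.number_of_edges() < 2:
        return 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = nx.degree_assortativity_coefficient(G)
    return float(r) if np.isfinite(r) else 0.0


def rich_club(network) -> float:
    """Mean rich-club coefficient phi(k) over degree levels k = 1..k_max.

    phi(k) = 2 E_{>k} / (N_{>k} (N_{>k} - 1)) over the subgraph of nodes with
    degree > k; levels with fewer than two qualifying nodes are skipped.
    """
    W = _validate(_as_matrix(network))
    A = (W > 0)
    deg = A.sum(axis=1)
    kmax = int(deg.max()) if deg.size else 0
    phis = []
    for k in range(1, kmax + 1):
        nodes = np.flatnonzero(deg > k)
        if nodes.size < 2:
            continue
        sub = A[np.ix_(nodes, nodes)]
        e = sub.sum() / 2
        phis.append(2.0 * e / (nodes.size * (nodes.size - 1)))
    return float(np.mean(phis)) if phis else 0.0


# ---------------------------------------------------------------------------
# degree-preserving null models
# ---------------------------------------------------------------------------

@dataclass
class NullEnsemble:
    """Summaries of a degree-preserving (Maslov–Sneppen) null ensemble.

    Weighted nulls reassign the observed weight multiset uniformly at random
    onto the rewired topology, so strength distributions are matched in
    aggregate while all degree sequences are preserved exactly.
    """

    n_nulls: int
    swaps_per_edge: int
    seed: int
    global_efficiencies: list[float] = field(default_factory=list)
    local_efficiencies: list[float] = field(default_factory=list)

    @property
    def mean_global(self) -> float:
        return float(np.mean(self.global_efficiencies))

    @property
    def mean_local(self) -> float:
        return float(np.mean(self.local_efficiencies))


def rewire_degree_preserving(A: np.ndarray, swaps_per_edge: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Maslov–Sneppen double-edge swaps on a binary adjacency matrix.

    Attempts ``swaps_per_edge * m`` swaps; proposals creating self-loops or
    multi-edges are rejected, so graphs with no valid swap (e.g. a triangle)
    are returned unchanged.
    """
    A = (np.asarray(A) > 0)
    ii, jj = np.nonzero(np.triu(A, 1))
    edges = np.column_stack([ii, jj]).astype(np.int64)
    m = len(edges)
    if m < 2:
        return A.astype(np.int8)
    n_attempts = swaps_per_edge * m
    pick = rng.integers(0, m, size=(n_attempts, 2)).astype(np.int64)
    flip = (rng.random(n_attempts) < 0.5)
    A8 = A.astype(np.int8)
    _rewire_kernel(A8, edges, pick, flip)
    return A8


@njit(cache=True)
def _rewire_kernel(A: np.ndarray, edges: np.ndarray, pick: np.ndarray,
                   flip: np.ndarray) -> None:
    for t in range(pick.shape[0]):
        e1, e2 = pick[t, 0], pick[t, 1]
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if flip[t]:
            c, d = d, c
        # proposed replacement edges: (a,c) and (b,d)
        if a == c or a == d or b == c or b == d:
            continue
        if A[a, c] or A[b, d]:
            continue
        A[a, b] = A[b, a] = 0
        A[c, d] = A[d, c] = 0
        A[a, c] = A[c, a] = 1
        A[b, d] = A[d, b] = 1
        edges[e1, 0], edges[e1, 1] = min(a, c), max(a, c)
        edges[e2, 0], edges[e2, 1] = min(b, d), max(b, d)


def _randomize_weights(A_null: np.ndarray, weights: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Place the observed weight multiset randomly on a rewired topology."""
    ii, jj = np.nonzero(np.triu(A_null, 1))
    perm = rng.permutation(weights)
    W = np.zeros(A_null.shape, dtype=float)
    W[ii, jj] = perm[: ii.size]
    return W + W.T


def degree_preserving_nulls(network, n_nulls: int = 100,
                            swaps_per_edge: int = 10, seed: int = 0,
                            distance: str = "inverse") -> NullEnsemble:
    """Build a null ensemble and record weighted efficiencies per member."""
    W = _validate(_as_matrix(network))
    A = (W > 0)
    obs_weights = W[np.triu(A, 1)]
    rng = np.random.default_rng(seed)
    ens = NullEnsemble(n_nulls=n_nulls, swaps_per_edge=swaps_per_edge,
                       seed=seed)
    for _ in range(n_nulls):
        A_null = rewire_degree_preserving(A, swaps_per_edge, rng)
        W_null = _randomize_weights(A_null, obs_weights, rng)
        ens.global_efficiencies.append(
            global_efficiency(W_null, weighted=True, distance=distance))
        ens.local_efficiencies.append(
            local_efficiency(W_null, weighted=True, distance=distance))
    return ens


def normalized_efficiencies(network, ensemble: NullEnsemble,
                            distance: str = "inverse") -> tuple[float, float]:
    """Observed weighted efficiencies divided by null-ensemble means."""
    W = _validate(_as_matrix(network))
    eg = global_efficiency(W, weighted=True, distance=distance)
    el = local_efficiency(W, weighted=True, distance=distance)
    mg, ml = ensemble.mean_global, ensemble.mean_local
    ng = eg / mg if mg > 0 else (1.0 if eg == 0 else float("inf"))
    nl = el / ml if ml > 0 else (1.0 if el == 0 else float("inf"))
    return ng, nl


# ---------------------------------------------------------------------------
# full metric vector
# ---------------------------------------------------------------------------

def compute_all(network, n_nulls: int = 100, swaps_per_edge: int = 10,
                seed: int = 0, distance: str = "inverse") -> dict[str, float]:
    """Compute the full 21-measure vector plus a disconnected-node flag.

    Characteristic path lengths carry an ``inf`` sentinel when the network
    has unreachable pairs; ``disconnected`` records this so downstream
    feature matrices can impute before model fitting.
    """
    W = _validate(_as_matrix(network))
    A = (W > 0).astype(float)
    n = W.shape[0]
    deg = A.sum(axis=1)
    out: dict[str, float] = {}
    out["density"] = float(A.sum() / (n * (n - 1))) if n > 1 else 0.0
    out["mean_degree"] = float(deg.mean()) if n else 0.0
    out["global_efficiency_b"] = global_efficiency(A, weighted=False)
    out["local_efficiency_b"] = local_efficiency(A, weighted=False)
    out["char_path_length_b"] = char_path_length(A, weighted=False)
    cb, tb = clustering_transitivity(A, weighted=False)
    out["clustering_b"], out["transitivity_b"] = cb, tb
    out["modularity_b"] = modularity(A, weighted=False, seed=seed)
    out["betweenness_b"] = mean_betweenness(A, weighted=False)
    out["mean_strength"] = float(W.sum(axis=1).mean()) if n else 0.0
    out["global_efficiency_w"] = global_efficiency(W, weighted=True,
                                                   distance=distance)
    out["local_efficiency_w"] = local_efficiency(W, weighted=True,
                                                 distance=distance)
    out["char_path_length_w"] = char_path_length(W, weighted=True,
                                                 distance=distance)
    cw, tw = clustering_transitivity(W, weighted=True)
    out["clustering_w"], out["transitivity_w"] = cw, tw
    out["modularity_w"] = modularity(W, weighted=True, seed=seed)
    out["betweenness_w"] = mean_betweenness(W, weighted=True,
                                            distance=distance)
    out["assortativity"] = assortativity(W)
    out["rich_club"] = rich_club(W)
    ens = degree_preserving_nulls(W, n_nulls=n_nulls,
                                  swaps_per_edge=swaps_per_edge, seed=seed,
                                  distance=distance)
    ng, nl = normalized_efficiencies(W, ens, distance=distance)
    out["norm_global_efficiency"] = ng
    out["norm_local_efficiency"] = nl
    out["disconnected"] = float(not np.isfinite(out["char_path_length_b"]))
    return out
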