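"""Independent brute-force graph-metric oracles for testing.

Deliberately naive implementations (Floyd-Warshall triple loops, explicit
simple-path enumeration, exhaustive set partitions) that share no code with
the package. Only usable on small graphs.
"""

from __future__ import annotations

import itertools

import numpy as np


def bf_distances(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def bf_char_path_length(adj: np.ndarray) -> float:
    d = bf_distances(adj)
    vals = [
        d[i, j]
        for i in range(len(d))
        for j in range(len(d))
        if i != j and np.isfinite(d[i, j])
    ]
    return float(np.mean(vals)) if vals else float("inf")


def bf_global_efficiency(adj: np.ndarray) -> float:
    d = bf_distances(adj)
    n = len(d)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1)) if n > 1 else 0.0


def bf_nodal_efficiency(adj: np.ndarray) -> np.ndarray:
    d = bf_distances(adj)
    n = len(d)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                out[i] += 1.0 / d[i, j]
    return out / (n - 1)


def bf_clustering_mean(adj: np.ndarray) -> float:
    n = adj.shape[0]
    cs = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(
            adj[a, b] for a, b in itertools.combinations(nbrs, 2)
        )
        cs.append(links / (k * (k - 1) / 2))
    return float(np.mean(cs))


def bf_local_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    effs = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            effs.append(0.0)
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        effs.append(bf_global_efficiency(sub))
    return float(np.mean(effs))


def _all_simple_paths(adj: np.ndarray, s: int, t: int) -> list[tuple[int, ...]]:
    n = adj.shape[0]
    paths = []

    def walk(node, visited):
        if node == t:
            paths.append(tuple(visited))
            return
        for nxt in range(n):
            if adj[node, nxt] and nxt not in visited:
                walk(nxt, visited + [nxt])

    walk(s, [s])
    return paths


def bf_betweenness(adj: np.ndarray) -> np.ndarray:
    """Unnormalized shortest-path betweenness by explicit path enumeration."""
    n = adj.shape[0]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s >= t:
                continue
            paths = _all_simple_paths(adj, s, t)
            if not paths:
                continue
            dmin = min(len(p) for p in paths)
            shortest = [p for p in paths if len(p) == dmin]
            for p in shortest:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(shortest)
    return bc  # each unordered pair counted once (undirected convention)


def bf_modularity(adj: np.ndarray, partition: list[set[int]]) -> float:
    """Q = sum_c (e_cc - a_c^2) computed from raw edge counts."""
    m2 = adj.sum()  # 2 * n_edges
    if m2 == 0:
        return 0.0
    q = 0.0
    for comm in partition:
        comm = list(comm)
        e_cc = adj[np.ix_(comm, comm)].sum() / m2
        a_c = adj[comm, :].sum() / m2
        q += e_cc - a_c**2
    return float(q)


def _set_partitions(items: list[int]):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] | {first}] + part[i + 1 :]
        yield part + [{first}]


def bf_best_modularity(adj: np.ndarray) -> tuple[list[set[int]], float]:
    """Exhaustive modularity maximization over all set partitions (tiny n)."""
    n = adj.shape[0]
    best_q, best_p = -np.inf, None
    for part in _set_partitions(list(range(n))):
        q = bf_modularity(adj, part)
        if q > best_q:
            best_q, best_p = q, part
    return best_p, best_q


def bf_phi(adj: np.ndarray, k: int) -> float:
    deg = adj.sum(axis=0)
    rich = [i for i in range(len(deg)) if deg[i] > k]
    if len(rich) < 2:
        return float("nan")
    e = sum(
        adj[a, b] for a, b in itertools.combinations(rich, 2)
    )
    return e / (len(rich) * (len(rich) - 1) / 2)


def bf_partial_corr_1cov(x, y, z) -> float:
    """First-order partial correlation via the recursive formula."""
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    return (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))


def random_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    adj = (rng.random((n, n)) < p).astype(int)
    adj = np.triu(adj, 1)
    return adj + adj.T
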