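"""Independent brute-force oracles used to check the package's fast paths.

Everything here is deliberately naive — triple enumeration, Floyd-Warshall,
explicit shortest-path enumeration, exhaustive set-partition search, normal
equations — and shares no code with the implementation under test.
"""

from __future__ import annotations

import itertools

import numpy as np


def clustering_by_triples(A: np.ndarray) -> float:
    """Average clustering via enumeration of all node triples."""
    N = A.shape[0]
    cs = []
    for v in range(N):
        nbrs = [u for u in range(N) if A[v, u]]
        d = len(nbrs)
        if d < 2:
            cs.append(0.0)
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2) if A[a, b])
        cs.append(links / (d * (d - 1) / 2))
    return float(np.mean(cs))


def floyd_warshall(A: np.ndarray) -> np.ndarray:
    N = A.shape[0]
    D = np.where(A > 0, 1.0, np.inf)
    np.fill_diagonal(D, 0.0)
    for k in range(N):
        for i in range(N):
            for j in range(N):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def harmonic_lp_by_floyd_warshall(A: np.ndarray) -> float:
    D = floyd_warshall(A)
    N = A.shape[0]
    inv = []
    for i in range(N):
        for j in range(N):
            if i != j:
                inv.append(0.0 if np.isinf(D[i, j]) else 1.0 / D[i, j])
    return 1.0 / float(np.mean(inv))


def _all_shortest_paths(A: np.ndarray, s: int, t: int) -> list[list[int]]:
    """Every shortest s-t path, by DFS constrained to a BFS distance map."""
    N = A.shape[0]
    dist = np.full(N, np.inf)
    dist[s] = 0
    frontier = [s]
    while frontier:
        nxt = []
        for u in frontier:
            for v in range(N):
                if A[u, v] and np.isinf(dist[v]):
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    if np.isinf(dist[t]):
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for v in range(N):
            if A[u, v] and dist[v] == dist[u] + 1:
                extend(path + [v])
    extend([s])
    return paths


def betweenness_by_path_enumeration(A: np.ndarray) -> np.ndarray:
    """Fractional betweenness over unordered pairs, counting explicit paths."""
    N = A.shape[0]
    bc = np.zeros(N)
    for s, t in itertools.combinations(range(N), 2):
        paths = _all_shortest_paths(A, s, t)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / len(paths)
    return bc


def set_partitions(items):
    """All set partitions of a list (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[head] + part[i]] + part[i + 1:]
        yield [[head]] + part


def modularity_of_partition(A: np.ndarray, blocks) -> float:
    m = A.sum() / 2.0
    q = 0.0
    for block in blocks:
        idx = np.asarray(block)
        e_c = A[np.ix_(idx, idx)].sum() / 2.0
        d_c = A[idx].sum()
        q += e_c / m - (d_c / (2 * m)) ** 2
    return float(q)


def max_modularity_exhaustive(A: np.ndarray) -> tuple[float, list]:
    """Maximum Q over every partition of the nodes (feasible up to n ~ 8)."""
    best_q, best = -np.inf, None
    for part in set_partitions(range(A.shape[0])):
        q = modularity_of_partition(A, part)
        if q > best_q:
            best_q, best = q, part
    return best_q, best


def residuals_by_normal_equations(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """OLS residuals via explicit (X'X)^-1 X'Y."""
    beta = np.linalg.solve(X.T @ X, X.T @ Y)
    return Y - X @ beta


def pearson_by_formula(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook covariance / sd product."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov / (x.std() * y.std()))


def top_k_edges(R: np.ndarray, K: int) -> set[tuple[int, int]]:
    """Sort-and-cut edge selection on |R| with (i, j) tie-break."""
    N = R.shape[0]
    pairs = [(i, j) for i in range(N) for j in range(i + 1, N)]
    pairs.sort(key=lambda p: (-abs(R[p]), p))
    return set(pairs[:K])


class UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y):
        self.parent[self.find(x)] = self.find(y)

    def n_components(self):
        return len({self.find(i) for i in range(len(self.parent))})


def connected_by_union_find(A: np.ndarray) -> bool:
    N = A.shape[0]
    uf = UnionFind(N)
    for i in range(N):
        for j in range(i + 1, N):
            if A[i, j]:
                uf.union(i, j)
    return uf.n_components() == 1


def bh_stepup(pvals, q):
    """Benjamini-Hochberg rejections by the literal step-up rule."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


def anova_f_by_sums_of_squares(samples) -> float:
    """One-way ANOVA F from explicit between/within sums of squares."""
    all_vals = np.concatenate(samples)
    grand = all_vals.mean()
    ss_between = sum(len(s) * (np.mean(s) - grand) ** 2 for s in samples)
    ss_within = sum(((np.asarray(s) - np.mean(s)) ** 2).sum() for s in samples)
    df_b = len(samples) - 1
    df_w = all_vals.size - len(samples)
    return float((ss_between / df_b) / (ss_within / df_w))


def pooled_t(a, b) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))


def random_graph(n: int, p: float, rng) -> np.ndarray:
    """Symmetric 0/1 adjacency with edge probability p, no self-loops."""
    A = (rng.random((n, n)) < p).astype(int)
    A = np.triu(A, 1)
    return A + A.T
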