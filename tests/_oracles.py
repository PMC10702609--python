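"""Independent brute-force oracles for small weighted graphs and for the
FDR procedures.  Deliberately naive (exhaustive enumeration, literal
textbook definitions) and kept free of any strucnet graph code."""

from itertools import combinations, permutations

import numpy as np


def oracle_clustering(w):
    """Onnela clustering by explicit triangle enumeration."""
    n = w.shape[0]
    c = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if w[i, j] > 0]
        k = len(nb)
        if k < 2:
            continue
        s = 0.0
        for j, l in combinations(nb, 2):
            if w[j, l] > 0:
                s += (w[i, j] * w[i, l] * w[j, l]) ** (1.0 / 3.0)
        c[i] = s / (k * (k - 1) / 2.0)
    return c, c.mean()


def oracle_shortest_paths(w):
    """All-pairs shortest 1/weight distances by exhaustive enumeration of
    simple paths (feasible for n ≤ 8)."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    nodes = list(range(n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            best = np.inf
            inner = [x for x in nodes if x not in (i, j)]
            for r in range(len(inner) + 1):
                for mid in permutations(inner, r):
                    path = (i, *mid, j)
                    length = 0.0
                    for a, b in zip(path[:-1], path[1:]):
                        if w[a, b] <= 0:
                            length = np.inf
                            break
                        length += 1.0 / w[a, b]
                    best = min(best, length)
            d[i, j] = best
    return d


def oracle_cpl(w):
    d = oracle_shortest_paths(w)
    off = ~np.eye(w.shape[0], dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        return float("nan"), int(off.sum())
    return d[finite].mean(), int((off & ~np.isfinite(d)).sum())


def oracle_global_efficiency(w):
    n = w.shape[0]
    if n < 2:
        return 0.0
    d = oracle_shortest_paths(w)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def oracle_local_efficiency(w):
    n = w.shape[0]
    e = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if w[i, j] > 0]
        if len(nb) < 2:
            continue
        sub = w[np.ix_(nb, nb)]
        e[i] = oracle_global_efficiency(sub)
    return e, e.mean()


def oracle_bh(pvals, q):
    """Literal BH step-up: largest k with p(k) ≤ kq/m, reject the k smallest."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def oracle_bh_adjusted(pvals):
    """Literal BH adjusted p: min over k ≥ rank of p(k)·m/k, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for rank0, idx in enumerate(order):
        best = min(min(p[order[k]] * m / (k + 1) for k in range(rank0, m)), 1.0)
        adj[idx] = best
    return adj


def oracle_bky(pvals, q):
    """Literal two-stage step-up definition."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    q1 = q / (1.0 + q)
    r1 = int(oracle_bh(p, q1).sum())
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    m0 = m - r1
    if m0 == 0:
        return np.ones(m, dtype=bool)
    return oracle_bh(p, q1 * m / m0)


def fixture_graphs(max_nodes=8, n_random=6, seed=123):
    """Named small graphs for metric/oracle equivalence checks."""
    rng = np.random.default_rng(seed)
    graphs = {}

    def sym(w):
        w = np.triu(w, 1)
        return w + w.T

    k3 = np.ones((3, 3)) - np.eye(3)
    graphs["K3_unit"] = k3
    graphs["K3_half"] = 0.5 * k3
    graphs["K4_unit"] = np.ones((4, 4)) - np.eye(4)
    star = np.zeros((4, 4))
    star[0, 1:] = star[1:, 0] = 1.0
    graphs["star3"] = star
    path = np.zeros((3, 3))
    path[0, 1] = path[1, 0] = path[1, 2] = path[2, 1] = 1.0
    graphs["path3"] = path
    dyads = np.zeros((4, 4))
    dyads[0, 1] = dyads[1, 0] = dyads[2, 3] = dyads[3, 2] = 1.0
    graphs["two_dyads"] = dyads
    graphs["edgeless5"] = np.zeros((5, 5))
    for g in range(n_random):
        n = int(rng.integers(4, max_nodes + 1))
        w = rng.uniform(0.05, 1.0, (n, n)) * (rng.random((n, n)) < 0.55)
        graphs[f"random{g}_n{n}"] = sym(w)
    return graphs
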