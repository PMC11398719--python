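"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the code paths under test: shortest paths by
Floyd-Warshall over explicit length matrices, efficiencies by direct
summation, clustering by triple loop, OLS by normal equations.
"""

import numpy as np


def floyd_warshall(weights: np.ndarray) -> np.ndarray:
    n = weights.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and weights[i, j] > 0:
                d[i, j] = 1.0 / weights[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def nodal_efficiency_brute(weights: np.ndarray) -> np.ndarray:
    n = weights.shape[0]
    d = floyd_warshall(weights)
    out = np.zeros(n)
    for j in range(n):
        acc = 0.0
        for i in range(n):
            if i != j and np.isfinite(d[i, j]):
                acc += 1.0 / d[i, j]
        out[j] = acc / (n - 1)
    return out


def local_efficiency_brute(weights: np.ndarray) -> np.ndarray:
    n = weights.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if weights[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        sub = weights[np.ix_(nbrs, nbrs)]
        d = floyd_warshall(sub)
        acc = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and np.isfinite(d[a, b]):
                    acc += 1.0 / d[a, b]
        out[i] = acc / (k * (k - 1))
    return out


def clustering_brute(weights: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering, triple loop, weights scaled by max."""
    n = weights.shape[0]
    mx = weights.max()
    if mx == 0:
        return np.zeros(n)
    w = weights / mx
    out = np.zeros(n)
    for i in range(n):
        k = int((weights[i] > 0).sum())
        if k < 2:
            continue
        acc = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    acc += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
        out[i] = acc / (k * (k - 1))
    return out


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """beta = (X'X)^{-1} X'y with an explicit intercept column."""
    Xc = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(Xc.T @ Xc, Xc.T @ y)


def random_weighted_graph(rng: np.random.Generator, n: int,
                          density: float = 0.5) -> np.ndarray:
    w = rng.random((n, n))
    keep = rng.random((n, n)) < density
    w = np.triu(w * keep, k=1)
    return w + w.T
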