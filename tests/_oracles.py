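"""Independent brute-force oracles used across the test suite.

Deliberately naive implementations (exhaustive path enumeration, direct
numerical optimization) kept free of any package internals.
"""

import itertools

import numpy as np
from scipy.optimize import minimize


def brute_force_paths(W):
    """All-pairs shortest distances and shortest path sets by enumeration.

    Edge length 1/|w|; enumerates every simple path between every node pair.
    Returns (dist matrix, {(i, j): [paths]} for i < j).
    """
    W = np.abs(np.asarray(W, dtype=float))
    p = W.shape[0]
    dist = np.full((p, p), np.inf)
    np.fill_diagonal(dist, 0.0)
    shortest = {}
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            others = [k for k in range(p) if k not in (i, j)]
            cands = []
            for r in range(len(others) + 1):
                for mid in itertools.permutations(others, r):
                    nodes = (i, *mid, j)
                    if all(W[a, b] > 1e-8 for a, b in zip(nodes, nodes[1:])):
                        d = sum(1.0 / W[a, b] for a, b in zip(nodes, nodes[1:]))
                        cands.append((d, nodes))
            if cands:
                dmin = min(d for d, _ in cands)
                dist[i, j] = dmin
                if i < j:
                    shortest[(i, j)] = [nodes for d, nodes in cands if d <= dmin * (1 + 1e-12)]
    return dist, shortest


def brute_force_closeness(W):
    dist, _ = brute_force_paths(W)
    p = dist.shape[0]
    out = np.zeros(p)
    for i in range(p):
        others = np.delete(dist[i], i)
        if np.all(np.isfinite(others)) and others.sum() > 0:
            out[i] = 1.0 / others.sum()
    return out


def brute_force_betweenness(W):
    _, shortest = brute_force_paths(W)
    p = np.asarray(W).shape[0]
    out = np.zeros(p)
    for (i, j), paths in shortest.items():
        for nodes in paths:
            for v in nodes[1:-1]:
                out[v] += 1.0 / len(paths)
    return out


def glasso_objective_oracle(S, lam, x0=None):
    """Direct numerical maximization of the penalized Gaussian log-likelihood.

    Parametrizes a symmetric 3x3 precision matrix by its 6 free entries and
    maximizes ``log det O - tr(S O) - lam * sum_{i != j} |O_ij|`` (the sum
    runs over ordered pairs) with Nelder-Mead.
    """
    S = np.asarray(S, dtype=float)
    assert S.shape == (3, 3)
    pairs = [(0, 1), (0, 2), (1, 2)]

    def unpack(x):
        O = np.diag(x[:3])
        for k, (i, j) in enumerate(pairs):
            O[i, j] = O[j, i] = x[3 + k]
        return O

    def neg_objective(x):
        O = unpack(x)
        vals = np.linalg.eigvalsh(O)
        if vals.min() <= 1e-10:
            return 1e12
        logdet = float(np.sum(np.log(vals)))
        return -(logdet - float(np.trace(S @ O)) - lam * 2.0 * np.sum(np.abs(x[3:])))

    if x0 is None:
        Oi = np.linalg.inv(S)
        x0 = np.array([Oi[0, 0], Oi[1, 1], Oi[2, 2], Oi[0, 1], Oi[0, 2], Oi[1, 2]])
    res = minimize(
        neg_objective,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 50000, "maxfev": 50000},
    )
    return unpack(res.x)
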