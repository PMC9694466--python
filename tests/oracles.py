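"""Independent oracles used by the test suite.

Each oracle is implemented by a different route than the code it checks:
quaternion (Horn) superposition vs the SVD Kabsch solver, Monte-Carlo
surface sampling vs the deterministic sphere lattice, power-iteration
committors and exhaustive simple-path enumeration vs the linear-algebra /
Dijkstra implementations.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def horn_rmsd(mobile, target, weights=None) -> float:
    """Optimal superposition RMSD by Horn's quaternion method."""
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    n = len(mobile)
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    mc = mobile - (w[:, None] * mobile).sum(0)
    tc = target - (w[:, None] * target).sum(0)
    s = (mc * w[:, None]).T @ tc
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    msd = (w[:, None] * (mc**2 + tc**2)).sum() - 2.0 * lam
    return float(np.sqrt(max(msd, 0.0)))


def mc_sasa(coords, radii, probe=1.4, n_samples=40000, seed=0) -> float:
    """Monte-Carlo estimate of total solvent-accessible surface area."""
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float) + probe
    total = 0.0
    for i in range(len(coords)):
        v = rng.standard_normal((n_samples, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        pts = coords[i] + radii[i] * v
        others = np.delete(np.arange(len(coords)), i)
        if len(others):
            d2 = ((pts[:, None, :] - coords[others][None, :, :]) ** 2).sum(2)
            frac = 1.0 - (d2 < (radii[others] ** 2)[None, :]).any(1).mean()
        else:
            frac = 1.0
        total += 4.0 * np.pi * radii[i] ** 2 * frac
    return float(total)


def committor_power_iteration(T, source, sink, n_iter=200000, tol=1e-13):
    """Forward committor by fixed-point iteration q <- T q with boundaries."""
    n = T.shape[0]
    q = np.zeros(n)
    q[list(sink)] = 1.0
    free = [i for i in range(n) if i not in set(source) | set(sink)]
    for _ in range(n_iter):
        q_new = q.copy()
        q_new[free] = (T @ q)[free]
        if np.max(np.abs(q_new - q)) < tol:
            return q_new
        q = q_new
    return q


def bruteforce_pathway_decomposition(net_flux, source, sink, rel_tol=1e-8):
    """Bottleneck pathway decomposition with exhaustive widest-path search.

    At every iteration, all simple source->sink paths on the current
    positive-flux graph are enumerated, the path with the largest
    bottleneck (lexicographically smallest among ties) is removed.
    """
    residual = np.array(net_flux, float)
    total = residual[list(source), :].sum() - residual[:, list(source)].sum()
    paths, fluxes = [], []
    while True:
        g = nx.DiGraph()
        n = residual.shape[0]
        g.add_nodes_from(range(n))
        for i in range(n):
            for j in range(n):
                if residual[i, j] > 0:
                    g.add_edge(i, j)
        best = None
        for s in sorted(source):
            for t in sorted(sink):
                if s not in g or t not in g:
                    continue
                for path in nx.all_simple_paths(g, s, t):
                    bn = min(residual[path[k], path[k + 1]] for k in range(len(path) - 1))
                    key = (-bn, tuple(path))
                    if best is None or key < best[0]:
                        best = (key, path, bn)
        if best is None or best[2] <= rel_tol * total:
            break
        _, path, bn = best
        for k in range(len(path) - 1):
            residual[path[k], path[k + 1]] -= bn
        paths.append(tuple(path))
        fluxes.append(bn)
        if sum(fluxes) >= total * (1 - rel_tol):
            break
    order = sorted(range(len(paths)), key=lambda i: (-fluxes[i], paths[i]))
    return [paths[i] for i in order], [fluxes[i] for i in order]


def all_paths_within(graph: nx.Graph, source, sink, bound, weight="weight"):
    """Exhaustive enumeration of simple paths with total weight <= bound."""
    out = []
    for path in nx.all_simple_paths(graph, source, sink):
        w = sum(graph[a][b][weight] for a, b in zip(path[:-1], path[1:]))
        if w <= bound + 1e-12:
            out.append((w, tuple(path)))
    out.sort()
    return out


def random_reversible_chain(n, rng):
    """Random reversible row-stochastic matrix with its stationary vector."""
    w = rng.random((n, n)) + 0.05
    w = 0.5 * (w + w.T)  # symmetric positive weights -> reversible chain
    T = w / w.sum(1)[:, None]
    pi = w.sum(1) / w.sum()
    return T, pi


def brute_modularity_best_2partition(graph: nx.Graph, weight=None):
    """Best 2-community partition by exhaustive search over bipartitions."""
    nodes = sorted(graph.nodes)
    best, best_q = None, -np.inf
    for r in range(1, len(nodes) // 2 + 1):
        for combo in itertools.combinations(nodes, r):
            part = [set(combo), set(nodes) - set(combo)]
            q = nx.community.modularity(graph, part, weight=weight)
            if q > best_q:
                best, best_q = part, q
    return best, best_q
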