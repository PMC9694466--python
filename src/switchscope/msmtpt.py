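"""Markov state models and transition path theory for loop dynamics.

Workflow: featurize frames on the flexible (high-RMSF) residues, k-means
cluster into microstates, estimate a (by default reversible) transition
matrix at a lag time, coarse-grain into metastates by a PCCA-style
spectral method, and decompose the reactive source→sink flux into
pathways whose cumulative share identifies the dominant metastates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .geomcore import superpose_frames
from .system import ParamStructure, Trajectory


class MsmError(ValueError):
    pass


# ---------------------------------------------------------------------------
# featurization and clustering
# ---------------------------------------------------------------------------

def featurize(traj: Trajectory, structure: ParamStructure, flexible_resids) -> np.ndarray:
    """Flattened 3D bead coordinates of the flexible residues, frames
    superposed on the non-flexible protein beads."""
    flexible_resids = sorted(set(int(r) for r in flexible_resids))
    if not flexible_resids:
        raise MsmError("empty flexible set: lower the RMSF threshold")
    beads = structure.beads()
    bead_resids = structure.resids[beads]
    flex_mask = np.isin(bead_resids, flexible_resids)
    if not flex_mask.any():
        raise MsmError("no beads match the flexible residues")
    fit_sel = beads[~flex_mask] if (~flex_mask).any() else beads
    fitted = superpose_frames(traj.coords, traj.coords[traj.ref_frame], fit_sel)
    return fitted[:, beads[flex_mask], :].reshape(traj.n_frames, -1)


def cluster_microstates(features, k: int, seed: int = 0):
    """Seeded k-means++ clustering; returns (discrete trajectory, centers)."""
    features = np.asarray(features, dtype=float)
    n_distinct = len(np.unique(features, axis=0))
    if k > len(features):
        raise MsmError(f"k={k} exceeds {len(features)} frames")
    if k > n_distinct:
        raise MsmError(f"k={k} exceeds {n_distinct} distinct points")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, random_state=seed)
    labels = km.fit_predict(features)
    return labels.astype(int), km.cluster_centers_


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

@dataclass
class MsmModel:
    dtraj: np.ndarray                  # frame -> microstate id (original labels)
    lag: int
    counts: np.ndarray                 # count matrix on the active set
    T: np.ndarray                      # row-stochastic transition matrix
    pi: np.ndarray                     # stationary distribution
    timescales: np.ndarray             # implied timescales, lag units, descending
    active: np.ndarray                 # microstate ids in the largest connected set
    centers: np.ndarray | None = None  # microstate centers in feature space
    memberships: np.ndarray | None = None   # microstate -> metastate weights
    metastates: np.ndarray | None = None    # crisp metastate per active microstate

    def __post_init__(self):
        if not np.allclose(self.T.sum(axis=1), 1.0, atol=1e-10):
            raise MsmError("transition matrix rows must sum to 1")
        if np.any(self.pi < -1e-12) or abs(self.pi.sum() - 1.0) > 1e-8:
            raise MsmError("stationary distribution must be a probability vector")
        if np.max(np.abs(self.pi @ self.T - self.pi)) > 1e-8:
            raise MsmError("pi is not stationary under T")

    def metastate_weights(self) -> np.ndarray:
        """Stationary weight of each metastate (sums to 1)."""
        if self.metastates is None:
            raise MsmError("metastates not assigned")
        n_meta = int(self.metastates.max()) + 1
        return np.array([self.pi[self.metastates == m].sum() for m in range(n_meta)])


def count_transitions(dtraj, lag: int, n_states: int | None = None) -> np.ndarray:
    """Sliding-window transition counts at the given lag."""
    dtraj = np.asarray(dtraj, dtype=int)
    if lag < 1:
        raise MsmError("lag must be >= 1")
    if n_states is None:
        n_states = int(dtraj.max()) + 1
    c = np.zeros((n_states, n_states))
    np.add.at(c, (dtraj[:-lag], dtraj[lag:]), 1.0)
    return c


def _largest_connected(counts: np.ndarray) -> np.ndarray:
    import scipy.sparse.csgraph as csg

    n, labels = csg.connected_components(counts > 0, directed=True, connection="strong")
    if n == 1:
        return np.arange(counts.shape[0])
    pops = counts.sum(axis=1)
    best = max(range(n), key=lambda c: pops[labels == c].sum())
    return np.flatnonzero(labels == best)


def estimate_msm(dtraj, lag: int, reversible: bool = True,
                 centers=None, warn=None) -> MsmModel:
    """Estimate a Markov state model from a discrete trajectory.

    Counts are symmetrized (C ← (C+Cᵀ)/2) when ``reversible`` (default),
    then row-normalized on the largest strongly connected set; the
    stationary distribution is the leading left eigenvector and implied
    timescales are t_i = −lag / ln λ_i.
    """
    import warnings as _warnings

    dtraj = np.asarray(dtraj, dtype=int)
    counts_full = count_transitions(dtraj, lag)
    visited = np.flatnonzero(counts_full.sum(axis=1) + counts_full.sum(axis=0) > 0)
    active = _largest_connected(counts_full[np.ix_(visited, visited)])
    active = visited[active]
    if len(active) < len(visited):
        _warnings.warn(
            f"disconnected chain: restricting to {len(active)} of {len(visited)} states",
            stacklevel=2,
        )
    c = counts_full[np.ix_(active, active)]
    if reversible:
        c = 0.5 * (c + c.T)
    rowsum = c.sum(axis=1)
    if np.any(rowsum == 0):
        raise MsmError("empty row in restricted count matrix")
    T = c / rowsum[:, None]
    vals, vecs = np.linalg.eig(T.T)
    order = np.argsort(-np.abs(vals))
    vals, vecs = vals[order], vecs[:, order]
    pi = np.abs(np.real(vecs[:, 0]))
    pi = pi / pi.sum()
    lam = np.real(vals[1:])
    lam = lam[(lam > 1e-12) & (lam < 1.0)]
    ts = -lag / np.log(lam)
    ts = np.sort(ts)[::-1]
    return MsmModel(
        dtraj=dtraj, lag=lag, counts=c, T=T, pi=pi, timescales=ts,
        active=active, centers=None if centers is None else np.asarray(centers),
    )


# ---------------------------------------------------------------------------
# PCCA-style coarse graining
# ---------------------------------------------------------------------------

def coarse_grain_metastates(model: MsmModel, n_meta: int) -> MsmModel:
    """Spectral fuzzy metastate memberships from the top right eigenvectors.

    Classic inner-simplex construction: pick the n_meta mutually most
    distant states in eigenvector space as vertices, express every state in
    their barycentric basis, clip and renormalize.  Crisp assignment is
    the argmax membership.  Returns the model with ``memberships`` and
    ``metastates`` filled in.
    """
    n = model.T.shape[0]
    if not 2 <= n_meta <= n:
        raise MsmError("need 2 <= n_meta <= number of microstates")
    vals, vecs = np.linalg.eig(model.T)
    order = np.argsort(-np.real(vals) - 1e-12 * np.abs(np.imag(vals)))
    vals = vals[order][:n_meta]
    if np.max(np.abs(np.imag(vals))) > 1e-8:
        raise MsmError("complex dominant eigenvalues; use reversible estimation")
    psi = np.real(vecs[:, order[:n_meta]])
    psi[:, 0] = 1.0
    # inner-simplex vertex search
    idx = [int(np.argmax(np.linalg.norm(psi - psi.mean(axis=0), axis=1)))]
    basis = psi - psi[idx[0]]
    for _ in range(1, n_meta):
        # Gram-Schmidt against already chosen vertex directions
        chosen = basis[idx[1:]] if len(idx) > 1 else np.empty((0, n_meta))
        q = []
        for row in chosen:
            r = row.copy()
            for u in q:
                r -= (r @ u) * u
            nr = np.linalg.norm(r)
            if nr > 1e-12:
                q.append(r / nr)
        resid = basis.copy()
        for u in q:
            resid -= np.outer(resid @ u, u)
        idx.append(int(np.argmax(np.linalg.norm(resid, axis=1))))
    a = np.linalg.inv(psi[idx])
    chi = psi @ a
    chi = np.clip(chi, 0.0, None)
    chi = chi / chi.sum(axis=1)[:, None]
    model.memberships = chi
    model.metastates = np.argmax(chi, axis=1)
    # relabel metastates by ascending index of their first member (determinism)
    seen = {}
    relabel = np.empty_like(model.metastates)
    for i, m in enumerate(model.metastates):
        if m not in seen:
            seen[m] = len(seen)
        relabel[i] = seen[m]
    perm = np.array([seen[m] for m in range(len(seen))] + [0] * 0)
    model.metastates = relabel
    cols = sorted(seen, key=lambda m: seen[m])
    model.memberships = chi[:, cols]
    return model


def coarse_grained_T(model: MsmModel) -> tuple[np.ndarray, np.ndarray]:
    """Metastate-level transition matrix and stationary weights
    (π-weighted crisp aggregation of the microstate matrix)."""
    if model.metastates is None:
        raise MsmError("metastates not assigned")
    n_meta = int(model.metastates.max()) + 1
    agg = np.zeros((len(model.pi), n_meta))
    agg[np.arange(len(model.pi)), model.metastates] = 1.0
    flux = agg.T @ (model.pi[:, None] * model.T) @ agg
    pi_meta = agg.T @ model.pi
    T_meta = flux / pi_meta[:, None]
    T_meta = T_meta / T_meta.sum(axis=1)[:, None]
    return T_meta, pi_meta


# ---------------------------------------------------------------------------
# transition path theory
# ---------------------------------------------------------------------------

@dataclass
class TptResult:
    source: tuple
    sink: tuple
    q_forward: np.ndarray
    q_backward: np.ndarray
    net_flux: np.ndarray
    total_flux: float
    pathways: list = field(default_factory=list)       # state sequences
    pathway_fluxes: list = field(default_factory=list)

    def cumulative_fraction(self) -> np.ndarray:
        f = np.asarray(self.pathway_fluxes)
        return np.cumsum(f) / self.total_flux


def committor(T, pi, source, sink):
    """Forward and backward committors of a Markov chain."""
    n = T.shape[0]
    source = sorted(set(int(s) for s in np.atleast_1d(source)))
    sink = sorted(set(int(s) for s in np.atleast_1d(sink)))
    if set(source) & set(sink):
        raise MsmError("source and sink must be disjoint")
    interior = np.array([i for i in range(n) if i not in source and i not in sink])
    qf = np.zeros(n)
    qf[sink] = 1.0
    if interior.size:
        A = np.eye(len(interior)) - T[np.ix_(interior, interior)]
        b = T[np.ix_(interior, sink)].sum(axis=1)
        qf[interior] = np.linalg.solve(A, b)
    # backward committor via the time-reversed chain
    Tb = (pi[None, :] * T.T) / pi[:, None]
    qb = np.zeros(n)
    qb[source] = 1.0
    if interior.size:
        A = np.eye(len(interior)) - Tb[np.ix_(interior, interior)]
        b = Tb[np.ix_(interior, source)].sum(axis=1)
        qb[interior] = np.linalg.solve(A, b)
    return qf, qb


def tpt_flux_pathways(T, pi, source, sink, rel_tol: float = 1e-8) -> TptResult:
    """Reactive flux analysis: committors, net flux, bottleneck pathways.

    The gross flux f_ij = π_i q⁻_i T_ij q⁺_j (i≠j) is antisymmetrized to
    f⁺ = max(0, f − fᵀ) and decomposed by repeatedly removing the pathway
    with the largest bottleneck until the residual drops below ``rel_tol``
    of the total source→sink flux.  Ties between equal-bottleneck pathways
    are broken lexicographically by state sequence.
    """
    T = np.asarray(T, dtype=float)
    pi = np.asarray(pi, dtype=float)
    source = sorted(set(int(s) for s in np.atleast_1d(source)))
    sink = sorted(set(int(s) for s in np.atleast_1d(sink)))
    qf, qb = committor(T, pi, source, sink)
    n = T.shape[0]
    f = pi[:, None] * qb[:, None] * T * qf[None, :]
    np.fill_diagonal(f, 0.0)
    net = np.maximum(0.0, f - f.T)
    total = float(net[source, :].sum() - net[:, source].sum())
    if total <= 0:
        raise MsmError("total reactive flux is zero")
    residual = net.copy()
    pathways, fluxes = [], []
    while True:
        path = _best_bottleneck_path(residual, source, sink)
        if path is None:
            break
        bn = min(residual[path[i], path[i + 1]] for i in range(len(path) - 1))
        if bn <= rel_tol * total:
            break
        for i in range(len(path) - 1):
            residual[path[i], path[i + 1]] -= bn
        pathways.append(tuple(path))
        fluxes.append(float(bn))
        if sum(fluxes) >= total * (1.0 - rel_tol):
            break
    order = sorted(range(len(pathways)), key=lambda i: (-fluxes[i], pathways[i]))
    return TptResult(
        source=tuple(source), sink=tuple(sink), q_forward=qf, q_backward=qb,
        net_flux=net, total_flux=total,
        pathways=[pathways[i] for i in order],
        pathway_fluxes=[fluxes[i] for i in order],
    )


def _best_bottleneck_path(flux, source, sink):
    """Widest path (max bottleneck) from any source to any sink state;
    lexicographically smallest among equal-bottleneck paths.

    The bottleneck value is found by a Dijkstra-style widest-path sweep;
    the path itself is the first source→sink route found by an
    ascending-order depth-first search on the subgraph of edges carrying
    at least that flux, which is the lexicographically smallest one.
    """
    n = flux.shape[0]
    width = np.full(n, 0.0)
    visited = np.zeros(n, dtype=bool)
    for s in source:
        width[s] = np.inf
    for _ in range(n):
        cand = np.flatnonzero(~visited & (width > 0))
        if cand.size == 0:
            break
        u = int(cand[np.argmax(width[cand])])
        visited[u] = True
        w_new = np.minimum(width[u], flux[u])
        better = (~visited) & (w_new > width)
        width[better] = w_new[better]
    bottleneck = max((width[t] for t in sink if np.isfinite(width[t])), default=0.0)
    if bottleneck <= 0:
        return None
    allowed = flux >= bottleneck
    sink_set = set(int(t) for t in sink)

    def dfs(node, path, on_path):
        if node in sink_set:
            return list(path)
        for v in np.flatnonzero(allowed[node]):
            v = int(v)
            if v in on_path:
                continue
            path.append(v)
            on_path.add(v)
            found = dfs(v, path, on_path)
            if found is not None:
                return found
            path.pop()
            on_path.remove(v)
        return None

    for s in sorted(int(x) for x in source):
        found = dfs(s, [s], {s})
        if found is not None:
            return found
    return None


def select_dominant_states(tpt: TptResult, threshold: float = 0.60):
    """Shortest pathway prefix whose cumulative flux fraction strictly
    exceeds ``threshold``; returns (selected pathways, per-state flux share)."""
    if tpt.total_flux <= 0:
        raise MsmError("total flux is zero")
    cum = tpt.cumulative_fraction()
    k = int(np.searchsorted(cum, threshold, side="right")) + 1
    k = min(k, len(tpt.pathways))
    selected = tpt.pathways[:k]
    share: dict[int, float] = {}
    for path, fl in zip(selected, tpt.pathway_fluxes[:k]):
        for s in path:
            share[int(s)] = share.get(int(s), 0.0) + fl / tpt.total_flux
    return selected, share


# ---------------------------------------------------------------------------
# representatives
# ---------------------------------------------------------------------------

def metastate_representatives(
    model: MsmModel,
    features,
    loop_rmsd: dict | None = None,
    n_rep: int = 10,
):
    """Representative frames per metastate and its loop-RMSD label.

    The n_rep frames nearest (Euclidean, feature space) to the metastate's
    π-weighted center are returned; the metastate's RMSD label is the mean
    loop RMSD over those frames.  The start state is the lowest-RMSD
    metastate, the end state the highest-population one.
    """
    import warnings as _warnings

    if model.metastates is None:
        raise MsmError("metastates not assigned")
    features = np.asarray(features, dtype=float)
    state_of_frame = model.dtraj
    micro_to_meta = {int(s): int(m) for s, m in zip(model.active, model.metastates)}
    out = {}
    n_meta = int(model.metastates.max()) + 1
    for m in range(n_meta):
        micro = model.active[model.metastates == m]
        frames = np.flatnonzero(np.isin(state_of_frame, micro))
        w = np.array([model.pi[int(np.flatnonzero(model.active == s)[0])] for s in micro])
        if model.centers is not None:
            center = (w[:, None] * model.centers[micro]).sum(axis=0) / w.sum()
        else:
            center = features[frames].mean(axis=0)
        if len(frames) < n_rep:
            _warnings.warn(f"metastate {m} has only {len(frames)} frames", stacklevel=2)
            reps = frames
        else:
            d = np.linalg.norm(features[frames] - center, axis=1)
            reps = frames[np.argsort(d, kind="stable")[:n_rep]]
        entry = {"frames": reps}
        if loop_rmsd is not None:
            entry["labels"] = {
                name: float(np.mean(np.asarray(series)[reps])) for name, series in loop_rmsd.items()
            }
            entry["rmsd_label"] = float(np.mean([entry["labels"][k] for k in entry["labels"]]))
        out[m] = entry
    weights = model.metastate_weights()
    meta_ids = sorted(out)
    if loop_rmsd is not None:
        start = min(meta_ids, key=lambda m: out[m]["rmsd_label"])
    else:
        start = meta_ids[0]
    end = int(np.argmax(weights))
    return out, start, end
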