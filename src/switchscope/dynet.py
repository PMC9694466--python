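"""Correlation-weighted dynamic network analysis.

Nodes are protein residues (via their Cα bead), individual ligand heavy
atoms, metal ions, and one reference atom of the nucleotide.  A pair of
nodes is connected when their minimum heavy-atom distance stays within the
contact cutoff (4.5 Å) for at least the persistence fraction (75%) of
frames, excluding sequence-adjacent residues; the edge weight is
w = −log|C_ij| from the motion correlation of the node representative
atoms, so strongly correlated contacts are "short".  Communities come
from weighted Girvan–Newman at maximum modularity; allosteric optimal and
suboptimal paths are the shortest and near-shortest simple paths between
chosen endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .geomcore import superpose_frames
from .system import ParamStructure, Trajectory

W_MAX = -float(np.log(1e-6))  # ≈ 13.8, weight cap for |C| below 1e-6


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class NetNode:
    label: str
    rep_atom: int            # atom whose motion defines the node position
    contact_atoms: tuple     # heavy atoms used for edge-distance tests
    resid: int | None = None # protein residue index, None for non-protein nodes


def network_nodes(structure: ParamStructure, nucleotide_ref: str = "C1'") -> list[NetNode]:
    """Node set: one node per protein residue (bead), one per ligand heavy
    atom, one per ion, one for the nucleotide at its reference atom."""
    nodes = []
    beads = structure.beads()
    for b in beads:
        resid = int(structure.resids[b])
        atoms = structure.residue_atoms(resid)
        heavy = tuple(int(a) for a in atoms if structure.heavy[a])
        nodes.append(NetNode(f"R{resid}", int(b), heavy, resid))
    for a in structure.atoms_by_role("ligand"):
        if structure.heavy[a]:
            nodes.append(NetNode(f"L:{structure.names[a]}", int(a), (int(a),)))
    nuc = structure.atoms_by_role("nucleotide")
    if nuc.size:
        ref = [a for a in nuc if structure.names[a] == nucleotide_ref]
        ref = int(ref[0]) if ref else int(nuc[0])
        nodes.append(NetNode("NUC", ref, tuple(int(a) for a in nuc if structure.heavy[a])))
    for a in structure.atoms_by_role("ion"):
        nodes.append(NetNode(f"ION:{structure.names[a]}", int(a), (int(a),)))
    return nodes


@dataclass
class DynamicNetwork:
    nodes: list
    correlation: np.ndarray      # C_ij between node representative atoms
    persistence: np.ndarray      # fraction of frames each pair is in contact
    graph: nx.Graph              # weighted edges (w = -log|C|)
    communities: list | None = None
    modularity: float | None = None


def build_network(
    traj: Trajectory,
    structure: ParamStructure,
    dist_cutoff: float = 4.5,
    persistence: float = 0.75,
    stride: int = 1,
    nodes: list | None = None,
    superpose: bool = True,
) -> DynamicNetwork:
    """Persistence-contact graph with correlation weights.

    An edge joins two nodes iff their minimum heavy-atom distance is
    ≤ ``dist_cutoff`` in at least ``persistence`` of the frames and the
    nodes are not sequence-adjacent residues (|i−j| ≤ 1 excluded).
    Correlations use scalar products of displacement vectors after
    superposition on the protein beads.
    """
    traj.check_structure(structure)
    if traj.n_frames < 2:
        raise NetworkError("need at least 2 frames")
    if nodes is None:
        nodes = network_nodes(structure)
    n = len(nodes)
    frames = np.arange(0, traj.n_frames, stride)
    beads = structure.beads()
    if superpose and len(beads) >= 3:
        fitted = superpose_frames(traj.coords[frames], traj.coords[traj.ref_frame], beads)
    else:
        fitted = traj.coords[frames]

    # persistence of min heavy-atom contact (vectorized via an
    # atom-to-node indicator: node pairs touch iff any atom pair does)
    contact_atoms = [np.array(nd.contact_atoms, dtype=int) for nd in nodes]
    atoms = np.unique(np.concatenate(contact_atoms))
    col = {int(a): k for k, a in enumerate(atoms)}
    z = np.zeros((len(atoms), n))
    for i, ca in enumerate(contact_atoms):
        for a in ca:
            z[col[int(a)], i] = 1.0
    persist = np.zeros((n, n))
    cut2 = dist_cutoff**2
    for f in range(len(frames)):
        x = fitted[f][atoms]
        d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
        touching = (z.T @ (d2 <= cut2) @ z) > 0
        persist += touching
    persist /= len(frames)
    np.fill_diagonal(persist, 1.0)

    # correlation of representative-atom displacements
    reps = np.array([nd.rep_atom for nd in nodes])
    pos = fitted[:, reps, :]
    dev = pos - pos.mean(axis=0)
    cov = np.einsum("fid,fjd->ij", dev, dev) / len(frames)
    var = np.diag(cov).copy()
    if np.any(var <= 1e-12):
        raise NetworkError("zero fluctuation: correlations undefined for a static trajectory")
    corr = cov / np.sqrt(np.outer(var, var))

    g = nx.Graph()
    for i, nd in enumerate(nodes):
        g.add_node(nd.label, resid=nd.resid)
    for i in range(n):
        for j in range(i + 1, n):
            if persist[i, j] < persistence:
                continue
            ri, rj = nodes[i].resid, nodes[j].resid
            if ri is not None and rj is not None and abs(ri - rj) <= 1:
                continue
            c = abs(corr[i, j])
            w = W_MAX if c < 1e-6 else min(-float(np.log(c)), W_MAX)
            g.add_edge(nodes[i].label, nodes[j].label, weight=w, correlation=float(corr[i, j]),
                       persistence=float(persist[i, j]))
    return DynamicNetwork(nodes=nodes, correlation=corr, persistence=persist, graph=g)


def detect_communities(net: DynamicNetwork) -> tuple[list, float]:
    """Weighted Girvan–Newman partition at maximum modularity.

    Edge removal uses betweenness with the network's distance weights;
    modularity is evaluated with the same weights.  Deterministic under
    networkx's stable orderings.  An edgeless graph gives singleton
    communities at modularity 0.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        communities = [{n} for n in sorted(g.nodes)]
        net.communities, net.modularity = communities, 0.0
        return communities, 0.0

    def most_valuable_edge(graph):
        bet = nx.edge_betweenness_centrality(graph, weight="weight")
        return max(sorted(bet), key=lambda e: bet[e])

    best, best_q = [set(c) for c in nx.connected_components(g)], nx.community.modularity(
        g, [set(c) for c in nx.connected_components(g)], weight="weight"
    )
    for partition in nx.community.girvan_newman(g, most_valuable_edge=most_valuable_edge):
        q = nx.community.modularity(g, partition, weight="weight")
        if q > best_q + 1e-12:
            best, best_q = [set(c) for c in partition], q
    net.communities, net.modularity = best, float(best_q)
    return best, float(best_q)


@dataclass
class PathReport:
    source: str
    sink: str
    optimal_path: tuple
    optimal_weight: float
    paths: list = field(default_factory=list)      # all paths within tolerance, sorted
    weights: list = field(default_factory=list)
    node_counts: dict = field(default_factory=dict)


def suboptimal_paths(net: DynamicNetwork, source: str, sink: str,
                     tolerance: float) -> PathReport:
    """Optimal (Dijkstra) and all suboptimal simple paths within
    ``tolerance`` weight units of optimal, by exhaustive branch-and-bound
    enumeration; per-node appearance counts across all reported paths."""
    g = net.graph
    for label in (source, sink):
        if label not in g:
            raise NetworkError(f"unknown node {label!r}")
    if not nx.has_path(g, source, sink):
        comp_s = nx.node_connected_component(g, source)
        comp_t = nx.node_connected_component(g, sink)
        raise NetworkError(
            f"{source!r} and {sink!r} are disconnected "
            f"(components of sizes {len(comp_s)} and {len(comp_t)})"
        )
    opt_w, opt_path = nx.single_source_dijkstra(g, source, sink, weight="weight")
    bound = opt_w + tolerance
    # admissible heuristic: exact remaining distance to the sink
    dist_to_sink = nx.single_source_dijkstra_path_length(g, sink, weight="weight")
    found = []

    def dfs(node, path, w):
        if w + dist_to_sink.get(node, np.inf) > bound + 1e-12:
            return
        if node == sink:
            found.append((w, tuple(path)))
            return
        for nbr in sorted(g.neighbors(node)):
            if nbr in path:
                continue
            path.append(nbr)
            dfs(nbr, path, w + g[node][nbr]["weight"])
            path.pop()

    dfs(source, [source], 0.0)
    found.sort(key=lambda t: (t[0], t[1]))
    counts: dict[str, int] = {}
    for _, p in found:
        for nd in p:
            counts[nd] = counts.get(nd, 0) + 1
    return PathReport(
        source=source, sink=sink,
        optimal_path=tuple(opt_path), optimal_weight=float(opt_w),
        paths=[p for _, p in found], weights=[w for w, _ in found],
        node_counts=counts,
    )


def allosteric_path_delta(report_a: PathReport, report_b: PathReport,
                          top: int = 5) -> dict:
    """Per-node signed difference of path appearance counts (B − A).

    Positive values mean more signal pathways pass through the node in
    system B.  Returns the full delta map plus the top increases and
    decreases."""
    union = set(report_a.node_counts) | set(report_b.node_counts)
    delta = {
        n: report_b.node_counts.get(n, 0) - report_a.node_counts.get(n, 0) for n in union
    }
    ordered = sorted(delta.items(), key=lambda kv: (-kv[1], kv[0]))
    increases = [kv for kv in ordered if kv[1] > 0][:top]
    decreases = [kv for kv in ordered[::-1] if kv[1] < 0][:top]
    return {"delta": dict(ordered), "top_increases": increases, "top_decreases": decreases}
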