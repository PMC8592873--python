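"""Dynamical residue contact networks for allosteric-path analysis.

The model
---------
Each protein residue is a node located at the per-frame mass-weighted center
of its heavy atoms.  An edge is drawn between two residues when any pair of
their heavy atoms stays within ``contact_cutoff`` (default 4.5 Å) in at
least ``occupancy_min`` (default 75%) of the ensemble frames.  The edge
weight is the coefficient of variation of the inter-node center-of-mass
distance series

    C_ij = Var(r_ij) / <r_ij>          (literal_var_over_mean, default)
    C_ij = Std(r_ij) / <r_ij>          (sqrt_var_over_mean)

so a mechanically stable contact (small relative distance fluctuation)
carries a small weight and "conducts" dynamic information well.  Because
C_ij depends only on internal distances, the construction is invariant to
global rigid-body motion and needs no prior frame alignment.

Allosteric pathways between two sites are minimum-weight paths in this
graph (Dijkstra with edge length C_ij).  Edge importance is scored by
weighted edge betweenness centrality (Brandes' algorithm, unnormalized
pair counts, co-optimal paths splitting counts equally), and "critical"
edges are those whose betweenness exceeds the mean of the edge-betweenness
distribution by ``sigma_k`` standard deviations (default 3).

Both moment conventions use population (1/F) averages: the frames are a
time average of one trajectory, not an n-sample estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .ensemble import Ensemble

__all__ = [
    "NetworkParams",
    "NodeDescriptor",
    "ContactNetwork",
    "PathResult",
    "residue_centers",
    "contact_occupancy",
    "build_network",
    "edge_betweenness",
    "critical_edges",
    "shortest_path",
    "interprotomer_edges",
]

#: atomic masses for the elements that occur in protein heavy atoms
ATOMIC_MASS = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "Se": 78.971, "F": 18.998, "Cl": 35.45,
    "Br": 79.904, "I": 126.904, "Fe": 55.845, "Zn": 65.38, "Mg": 24.305,
    "Ca": 40.078, "Na": 22.990, "K": 39.098, "Mn": 54.938, "Cu": 63.546,
}

WEIGHT_CONVENTIONS = ("literal_var_over_mean", "sqrt_var_over_mean")


@dataclass(frozen=True)
class NetworkParams:
    """Knobs of the network construction (defaults follow the study protocol)."""

    contact_cutoff: float = 4.5          # Å, heavy-atom contact distance
    occupancy_min: float = 0.75          # fraction of frames in contact
    sigma_k: float = 3.0                 # std-devs above the mean for critical edges
    weight_convention: str = "literal_var_over_mean"
    neighbor_exclusion: int = 1          # |Δresnum| excluded within a chain

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be positive")
        if not 0 < self.occupancy_min <= 1:
            raise ValueError("occupancy_min must be in (0, 1]")
        if self.sigma_k <= 0:
            raise ValueError("sigma_k must be positive")
        if self.weight_convention not in WEIGHT_CONVENTIONS:
            raise ValueError(f"weight_convention must be one of {WEIGHT_CONVENTIONS}")
        if self.neighbor_exclusion < 0:
            raise ValueError("neighbor_exclusion must be >= 0")


@dataclass
class NodeDescriptor:
    """One residue node: identity plus its per-frame heavy-atom center of mass."""

    chain_id: str
    residue_number: int
    residue_name: str
    centers: np.ndarray  # (F, 3) Å

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_number)

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.residue_number}"


@dataclass
class PathResult:
    """A minimum-weight path, its summed edge weight, and all co-optimal routes."""

    nodes: list[tuple[str, int]]
    path_weight: float
    alternates: list[list[tuple[str, int]]] = field(default_factory=list)
    found: bool = True

    @property
    def labels(self) -> list[str]:
        return [f"{c}:{n}" for c, n in self.nodes]


@dataclass
class ContactNetwork:
    """Residue graph with occupancy, mean distance and CV weight per edge.

    Node keys are ``(chain_id, residue_number)``; edge attributes are
    ``occupancy``, ``mean_distance``, ``weight`` (C_ij), and after
    :func:`edge_betweenness` also ``betweenness`` and ``critical``.
    """

    graph: nx.Graph
    params: NetworkParams
    nodes: list[NodeDescriptor] = field(default_factory=list)

    @property
    def betweenness_filled(self) -> bool:
        return all("betweenness" in d for _, _, d in self.graph.edges(data=True))

    def edge_records(self) -> list[dict]:
        recs = []
        for u, v, d in self.graph.edges(data=True):
            recs.append({
                "chain_i": u[0], "resnum_i": u[1], "chain_j": v[0], "resnum_j": v[1],
                **{k: d.get(k) for k in ("occupancy", "mean_distance", "weight",
                                         "betweenness", "critical")},
            })
        recs.sort(key=lambda r: (r["chain_i"], r["resnum_i"], r["chain_j"], r["resnum_j"]))
        return recs


def _heavy_info(ensemble: Ensemble, include_het: bool = False):
    """Flat heavy-atom indices, masses, residue assignment and node identities."""
    idx, masses, resid = [], [], []
    nodes = []
    i = 0
    for c in ensemble.topology.chains:
        for r in c.residues:
            use_res = not r.is_water and (include_het or not r.hetero)
            heavy = []
            for a in r.atoms:
                if use_res and a.element.upper() not in ("H", "D"):
                    heavy.append((i, a))
                i += 1
            if use_res:
                if not heavy:
                    raise ValueError(f"residue {c.chain_id}:{r.number} has no heavy atoms")
                for j, a in heavy:
                    idx.append(j)
                    try:
                        masses.append(ATOMIC_MASS[a.element.capitalize()])
                    except KeyError:
                        raise ValueError(f"no mass for element {a.element!r}") from None
                    resid.append(len(nodes))
                nodes.append((c.chain_id, r.number, r.name))
    return (np.asarray(idx, int), np.asarray(masses, float), np.asarray(resid, int), nodes)


def residue_centers(ensemble: Ensemble, include_het: bool = False) -> list[NodeDescriptor]:
    """Per-frame mass-weighted heavy-atom center of mass of every residue."""
    idx, masses, resid, ids = _heavy_info(ensemble, include_het)
    X = ensemble.frames[:, idx, :]                       # (F, nheavy, 3)
    n_res = len(ids)
    wsum = np.zeros(n_res)
    np.add.at(wsum, resid, masses)
    centers = np.zeros((ensemble.n_frames, n_res, 3))
    weighted = X * masses[None, :, None]
    for k in range(3):
        acc = np.zeros((ensemble.n_frames, n_res))
        np.add.at(acc.T, resid, weighted[:, :, k].T)
        centers[:, :, k] = acc / wsum[None, :]
    return [
        NodeDescriptor(chain_id=c, residue_number=n, residue_name=rn, centers=centers[:, i, :])
        for i, (c, n, rn) in enumerate(ids)
    ]


def contact_occupancy(
    ensemble: Ensemble, cutoff: float = 4.5, include_het: bool = False
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Fraction of frames in which residue pairs are in heavy-atom contact.

    Returns a symmetric (R, R) occupancy matrix (diagonal zero, by
    convention undefined) together with the ordered residue keys.  A pair
    counts as in contact in a frame when the minimum distance over its
    heavy-atom pairs is <= ``cutoff``.
    """
    idx, _masses, resid, ids = _heavy_info(ensemble, include_het)
    n_res = len(ids)
    counts = np.zeros((n_res, n_res), dtype=np.int64)
    for f in range(ensemble.n_frames):
        X = ensemble.frames[f][idx]
        pairs = cKDTree(X).query_pairs(cutoff, output_type="ndarray")
        if len(pairs):
            ri, rj = resid[pairs[:, 0]], resid[pairs[:, 1]]
            mask = ri != rj
            flat = np.unique(np.minimum(ri[mask], rj[mask]) * n_res + np.maximum(ri[mask], rj[mask]))
            counts.flat[flat] += 1
    occ = counts / ensemble.n_frames
    occ = occ + occ.T
    keys = [(c, n) for c, n, _ in ids]
    return occ, keys


def build_network(
    ensemble: Ensemble,
    params: NetworkParams | None = None,
    include_het: bool = False,
) -> ContactNetwork:
    """Build the weighted residue contact network from an ensemble.

    Edges require contact occupancy >= ``params.occupancy_min`` and, within
    a chain, sequence separation > ``params.neighbor_exclusion`` (covalently
    forced neighbor contacts would otherwise dominate every path).  Edge
    weights C_ij come from the center-of-mass distance series under the
    selected convention; the heavy-atom minimum-distance criterion is used
    only for the contact/occupancy test, matching the distinct roles the
    two distances play in the model.
    """
    params = params or NetworkParams()
    nodes = residue_centers(ensemble, include_het)
    if len(nodes) < 2:
        raise ValueError("need at least two residues to build a network")
    occ, keys = contact_occupancy(ensemble, params.contact_cutoff, include_het)
    centers = np.stack([n.centers for n in nodes], axis=1)  # (F, R, 3)

    G = nx.Graph()
    for n in nodes:
        G.add_node(n.key, chain=n.chain_id, resnum=n.residue_number, resname=n.residue_name)

    ii, jj = np.nonzero(np.triu(occ >= params.occupancy_min, k=1))
    for i, j in zip(ii, jj):
        ci, ri = keys[i]
        cj, rj = keys[j]
        if ci == cj and abs(ri - rj) <= params.neighbor_exclusion:
            continue
        d = np.linalg.norm(centers[:, i, :] - centers[:, j, :], axis=1)
        mean = float(d.mean())
        var = float(d.var())  # population moments
        if params.weight_convention == "literal_var_over_mean":
            w = var / mean
        else:
            w = float(np.sqrt(var)) / mean
        assert w >= 0.0
        G.add_edge(keys[i], keys[j], occupancy=float(occ[i, j]), mean_distance=mean, weight=w)
    return ContactNetwork(graph=G, params=params, nodes=nodes)


def edge_betweenness(network: ContactNetwork) -> ContactNetwork:
    """Fill weighted edge betweenness centralities (Brandes, unnormalized).

    Edge length is C_ij, so "shortest" means minimum summed relative
    distance fluctuation.  Counts are raw unordered reachable-pair counts;
    co-optimal paths split the count of their pair equally.
    """
    for _u, _v, d in network.graph.edges(data=True):
        assert d["weight"] >= 0.0, "negative edge weight is impossible by construction"
    bc = nx.edge_betweenness_centrality(network.graph, normalized=False, weight="weight")
    nx.set_edge_attributes(network.graph, {e: float(b) for e, b in bc.items()}, "betweenness")
    return network


def critical_edges(network: ContactNetwork, sigma_k: float | None = None) -> list[tuple]:
    """Edges whose betweenness exceeds mean + sigma_k * std of the distribution.

    With a degenerate (zero-spread) distribution the inequality is strict,
    so a uniform graph yields no critical edges.  Returns edges sorted by
    (betweenness desc, node labels).
    """
    if not network.betweenness_filled:
        edge_betweenness(network)
    sigma_k = network.params.sigma_k if sigma_k is None else sigma_k
    edges = list(network.graph.edges(data=True))
    if len(edges) < 2:
        warnings.warn("fewer than 2 edges: critical-edge distribution undefined")
        return []
    b = np.array([d["betweenness"] for _, _, d in edges])
    mean, sd = b.mean(), b.std()
    if sd == 0.0:
        crit = []  # strict inequality: nothing exceeds the mean
    else:
        thresh = mean + sigma_k * sd
        crit = [(u, v, d) for (u, v, d) in edges if d["betweenness"] >= thresh]
    flagged = {frozenset((u, v)) for u, v, _ in crit}
    for u, v, d in edges:
        d["critical"] = frozenset((u, v)) in flagged
    crit.sort(key=lambda e: (-e[2]["betweenness"], e[0], e[1]))
    return [(u, v) for u, v, _ in crit]


def _as_key(node):
    """Accept 'A:62' strings for residue nodes; pass other labels through."""
    if isinstance(node, str) and ":" in node:
        chain, _, num = node.partition(":")
        return (chain, int(num))
    if isinstance(node, list):
        return tuple(node)
    return node


def shortest_path(
    network: ContactNetwork, source, target, max_alternates: int = 100
) -> PathResult:
    """Minimum-weight (summed C_ij) path between two residues.

    All co-optimal paths are enumerated (up to ``max_alternates``) and
    ordered lexicographically by node labels; the first is reported as the
    path, the rest as alternates.  A disconnected pair yields an explicit
    not-found result rather than an exception.
    """
    s, t = _as_key(source), _as_key(target)
    G = network.graph
    for n in (s, t):
        if n not in G:
            raise KeyError(f"node {n} not in network")
    try:
        paths = []
        for p in nx.all_shortest_paths(G, s, t, weight="weight"):
            paths.append(list(p))
            if len(paths) >= max_alternates:
                break
    except nx.NetworkXNoPath:
        return PathResult(nodes=[], path_weight=float("inf"), found=False)
    paths.sort()
    best = paths[0]
    weight = float(sum(G.edges[u, v]["weight"] for u, v in zip(best, best[1:])))
    return PathResult(nodes=best, path_weight=weight, alternates=paths[1:])


def interprotomer_edges(network: ContactNetwork, critical_only: bool = False) -> list[tuple]:
    """Edges whose endpoints lie on different chains, betweenness-descending."""
    chains = {n[0] for n in network.graph.nodes}
    if len(chains) < 2:
        warnings.warn("single-chain network: no interprotomer edges possible")
        return []
    out = []
    for u, v, d in network.graph.edges(data=True):
        if u[0] != v[0] and (not critical_only or d.get("critical", False)):
            out.append((u, v, d))
    out.sort(key=lambda e: (-(e[2].get("betweenness") or 0.0), e[0], e[1]))
    return [(u, v) for u, v, _ in out]


def to_graphml(network: ContactNetwork, path) -> None:
    """Export with string node ids 'chain:resnum' and scalar attributes."""
    H = nx.Graph()
    for n, d in network.graph.nodes(data=True):
        H.add_node(f"{n[0]}:{n[1]}", **d)
    for u, v, d in network.graph.edges(data=True):
        attrs = {k: v2 for k, v2 in d.items() if v2 is not None}
        H.add_edge(f"{u[0]}:{u[1]}", f"{v[0]}:{v[1]}", **attrs)
    nx.write_graphml(H, path)


def edge_table(network: ContactNetwork):
    """Edge statistics as a pandas DataFrame (TSV-friendly)."""
    import pandas as pd

    return pd.DataFrame(network.edge_records())
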