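"""Graph-topology summaries of a predicted regulatory network.

All summary metrics use the undirected simple-graph convention common to
interactive network analyzers: parallel/antiparallel edges are merged and
self-loops dropped (both counted and reported, so the raw and simple edge
counts are inspectable side by side). The node-wise clustering
coefficient is 2*triangles / (deg*(deg-1)) for degree >= 2 and 0
otherwise, averaged over all nodes; path metrics are pooled over
connected ordered pairs only; the diameter is the largest finite
eccentricity. The degree distribution P(k) and a descriptive least-
squares power-law fit on log10 P(k) vs log10 k characterize scale-free
behaviour (this is a display-style fit, not a maximum-likelihood
exponent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .exceptions import InputError, ParameterError
from .io import RegulatoryNetwork

__all__ = ["TopologySummary", "summarize_topology", "degree_distribution"]


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges_raw: int
    n_edges_simple: int
    n_self_loops: int
    n_components: int
    clustering_coefficient: float
    characteristic_path_length: float
    diameter: int
    avg_neighbours: float
    degree_histogram: dict[int, int]
    power_law: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "n_nodes": self.n_nodes,
            "n_edges_raw": self.n_edges_raw,
            "n_edges_simple": self.n_edges_simple,
            "n_self_loops": self.n_self_loops,
            "n_components": self.n_components,
            "clustering_coefficient": self.clustering_coefficient,
            "characteristic_path_length": self.characteristic_path_length,
            "diameter": self.diameter,
            "avg_neighbours": self.avg_neighbours,
            "degree_histogram": {str(k): v for k, v in
                                 sorted(self.degree_histogram.items())},
            "power_law": dict(self.power_law),
        }
        return d


def _simple_graph(net: RegulatoryNetwork) -> tuple[nx.Graph, int]:
    """Undirected simple graph from the edge list; returns (G, n_self_loops)."""
    if net.n_edges == 0:
        raise InputError("cannot summarize an empty network")
    g = nx.Graph()
    self_loops = 0
    for row in net.edges.itertuples(index=False):
        if row.tf == row.target:
            self_loops += 1
            continue
        g.add_edge(row.tf, row.target)
    if g.number_of_nodes() == 0:
        raise InputError("network contains only self-loops")
    return g, self_loops


def _power_law_fit(pk: dict[int, float]) -> dict[str, float]:
    """Least-squares fit of log10 P(k) against log10 k over observed degrees."""
    ks = np.array([k for k in sorted(pk) if k > 0 and pk[k] > 0], dtype=float)
    if ks.size < 2:
        return {"slope": float("nan"), "intercept": float("nan"), "r2": float("nan")}
    x = np.log10(ks)
    y = np.log10(np.array([pk[int(k)] for k in ks]))
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return {"slope": float(slope), "intercept": float(intercept), "r2": r2}


def summarize_topology(net: RegulatoryNetwork) -> TopologySummary:
    """Compute the standard topology statistics of a regulatory network."""
    g, self_loops = _simple_graph(net)
    n = g.number_of_nodes()
    components = list(nx.connected_components(g))

    # mean shortest-path length over connected ordered pairs, pooled across
    # components; diameter = max finite eccentricity
    total_len = 0
    total_pairs = 0
    diameter = 0
    for comp in components:
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            for other, d in dists.items():
                if d > 0:
                    total_len += d
                    total_pairs += 1
                    diameter = max(diameter, d)
    cpl = total_len / total_pairs if total_pairs else float("nan")

    degrees = dict(g.degree())
    hist: dict[int, int] = {}
    for d in degrees.values():
        hist[d] = hist.get(d, 0) + 1
    pk = {k: c / n for k, c in hist.items()}

    return TopologySummary(
        n_nodes=n,
        n_edges_raw=net.n_edges,
        n_edges_simple=g.number_of_edges(),
        n_self_loops=self_loops,
        n_components=len(components),
        clustering_coefficient=float(nx.average_clustering(g)),
        characteristic_path_length=cpl,
        diameter=diameter,
        avg_neighbours=2.0 * g.number_of_edges() / n,
        degree_histogram=hist,
        power_law=_power_law_fit(pk),
    )


def degree_distribution(
    net: RegulatoryNetwork, mode: str = "undirected"
) -> tuple[dict[int, int], dict[int, float]]:
    """Degree histogram and normalized P(k).

    ``mode``: ``undirected`` (simple graph), ``out`` (TF out-degree on
    the directed graph) or ``in`` (target in-degree).
    """
    if mode == "undirected":
        g, _ = _simple_graph(net)
        degrees = [d for _, d in g.degree()]
    elif mode in ("out", "in"):
        if net.n_edges == 0:
            raise InputError("cannot summarize an empty network")
        dg = nx.DiGraph()
        dg.add_edges_from(net.edges[["tf", "target"]].itertuples(index=False))
        deg_view = dg.out_degree() if mode == "out" else dg.in_degree()
        degrees = [d for _, d in deg_view]
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    hist: dict[int, int] = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    n = len(degrees)
    pk = {k: c / n for k, c in hist.items()}
    return hist, pk
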