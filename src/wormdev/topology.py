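"""Small-world topology metrics on staged networks.

Clustering coefficient C and characteristic path length L follow the
Watts–Strogatz formulation on the symmetrized simple graph (an undirected
edge wherever any arc links a pair). Per developmental stage, C and L are
compared with Erdős–Rényi G(n, m) baselines matched on node and link
counts; C/C_rand well above 1 with L/L_rand near 1 is the small-world
signature.
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .connectome import Connectome
from .nulls import _trial_seed, erdos_renyi

__all__ = [
    "SmallWorldReport",
    "clustering_coefficient",
    "characteristic_path_length",
    "small_world_series",
]


@dataclass(frozen=True)
class SmallWorldReport:
    """Per-stage small-world summary against a matched Erdős–Rényi ensemble.

    ``lcc_fraction`` is the share of nodes in the largest connected
    component over which L was computed. Ratio fields are None when the
    stage network has no edges or the baseline is degenerate.
    """

    stage_time: float
    n_nodes: int
    n_links: int
    C: float | None
    L: float | None
    C_rand: float | None
    L_rand: float | None
    ratio_C: float | None
    ratio_L: float | None
    n_random: int
    lcc_fraction: float | None


def clustering_coefficient(connectome: Connectome | nx.Graph) -> float:
    """Mean local clustering over all nodes of the symmetrized graph.

    Each node contributes (triangles through it) / (k(k-1)/2); nodes of
    degree < 2 contribute 0 (they are included in the average, one of the
    two common conventions — it lowers C relative to excluding them).
    """
    g = connectome if isinstance(connectome, nx.Graph) else connectome.to_undirected_graph()
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    return float(nx.average_clustering(g, count_zeros=True))


def characteristic_path_length(connectome: Connectome | nx.Graph) -> float:
    """Mean shortest-path length over connected pairs in the largest component.

    Early-stage networks can be disconnected; L is then computed within the
    largest connected component (the component coverage is reported by
    :func:`small_world_series` so the approximation stays visible).
    """
    g = connectome if isinstance(connectome, nx.Graph) else connectome.to_undirected_graph()
    if g.number_of_edges() == 0:
        raise ValueError("edgeless graph")
    lcc = max(nx.connected_components(g), key=len)
    return float(nx.average_shortest_path_length(g.subgraph(lcc)))


def small_world_series(
    connectome: Connectome,
    stage_times=None,
    n_random: int = 20,
    seed: int = 0,
) -> list[SmallWorldReport]:
    """C, L and their Erdős–Rényi ratios at each developmental stage.

    Baselines are ensemble means over ``n_random`` G(n, m) graphs matched
    on the staged network's node and link counts. A stage with no links is
    reported with missing ratios rather than raising.
    """
    stage_times = (
        connectome.config.stage_times if stage_times is None else tuple(stage_times)
    )
    reports: list[SmallWorldReport] = []
    for si, t in enumerate(stage_times):
        staged = connectome.stage_network(t)
        g = staged.to_undirected_graph()
        n, m = g.number_of_nodes(), g.number_of_edges()
        if n == 0 or m == 0:
            reports.append(
                SmallWorldReport(t, n, m, None, None, None, None, None, None, n_random, None)
            )
            continue
        C = clustering_coefficient(g)
        L = characteristic_path_length(g)
        lcc = max(nx.connected_components(g), key=len)
        c_vals, l_vals = [], []
        for i in range(n_random):
            er = erdos_renyi(n, m, _trial_seed(seed, si * n_random + i))
            ge = er.to_undirected_graph()
            c_vals.append(clustering_coefficient(ge))
            try:
                l_vals.append(characteristic_path_length(ge))
            except ValueError:
                pass
        C_rand = float(np.mean(c_vals)) if c_vals else None
        L_rand = float(np.mean(l_vals)) if l_vals else None
        reports.append(
            SmallWorldReport(
                stage_time=t,
                n_nodes=n,
                n_links=m,
                C=C,
                L=L,
                C_rand=C_rand,
                L_rand=L_rand,
                ratio_C=(C / C_rand) if C_rand else None,
                ratio_L=(L / L_rand) if L_rand else None,
                n_random=n_random,
                lcc_fraction=len(lcc) / n,
            )
        )
    return reports
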