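"""Network and inequality measures of trophallactic activity.

The trophallactic network has one node per colony member (isolated, inactive
ants included) and a directed edge donor -> receiver weighted by the number
of events between that ordered pair.  Distances are unweighted hop counts;
by convention efficiency and clustering are computed on the undirected
projection and betweenness on the directed graph, switchable via flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from trophallaxis.model_core import Caste

__all__ = [
    "TrophallaxisNetwork", "ActivityProfile",
    "build_network", "global_efficiency", "node_centralities",
    "lorenz_gini", "t50", "activity_distributions",
]


@dataclass
class TrophallaxisNetwork:
    """Weighted directed exchange graph plus the full colony roster."""

    graph: nx.DiGraph  # nodes carry 'caste'; edges carry 'weight' (count) and 'amount'

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def undirected(self) -> nx.Graph:
        return self.graph.to_undirected(as_view=False)

    def edge_list(self) -> pd.DataFrame:
        rows = [(u, v, d["weight"], d["amount"]) for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["donor_id", "receiver_id", "weight", "amount"])


def _roster_castes(roster, caste_labels: Optional[Mapping[int, Caste]]) -> dict[int, Caste]:
    if caste_labels is not None:
        return {int(i): caste_labels[i] for i in roster}
    return {int(i): Caste.NF for i in roster}


def build_network(events: Iterable, roster: Sequence[int],
                  caste_labels: Optional[Mapping[int, Caste]] = None) -> TrophallaxisNetwork:
    """Aggregate an event log into the weighted directed exchange network.

    ``roster`` lists every colony member; ants without events remain as
    isolated nodes.  Events mentioning ids outside the roster are a data
    error.
    """
    castes = _roster_castes(roster, caste_labels)
    g = nx.DiGraph()
    for i, caste in castes.items():
        g.add_node(i, caste=caste.value)
    for ev in events:
        d, r = int(ev.donor_id), int(ev.receiver_id)
        if d not in castes or r not in castes:
            raise ValueError(f"event references ant(s) {d}->{r} missing from the roster")
        if g.has_edge(d, r):
            g[d][r]["weight"] += 1
            g[d][r]["amount"] += float(ev.amount)
        else:
            g.add_edge(d, r, weight=1, amount=float(ev.amount))
    return TrophallaxisNetwork(graph=g)


def global_efficiency(net: TrophallaxisNetwork, directed: bool = False) -> float:
    """Mean over ordered node pairs of the inverse shortest-path hop distance.

    Disconnected pairs contribute 0 (1/inf).  Defaults to the undirected
    projection; set ``directed=True`` to respect edge direction.
    """
    if net.n_nodes < 2:
        raise ValueError("efficiency is undefined for fewer than 2 nodes")
    g = net.graph if directed else net.undirected()
    n = g.number_of_nodes()
    total = 0.0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        total += sum(1.0 / d for d in dists.values() if d > 0)
    return total / (n * (n - 1))


def node_centralities(net: TrophallaxisNetwork, betweenness_directed: bool = True,
                      closeness_directed: bool = False) -> pd.DataFrame:
    """Per-node closeness, betweenness and clustering coefficients.

    Closeness is hop-count based and component-normalized (the networkx
    Wasserman-Faust-free convention: (r-1)/sum(d) * (r-1)/(n-1) over the r
    reachable nodes), so isolates get 0.  Betweenness is the normalized
    fraction of shortest paths through the node (directed by default);
    clustering is triangle transitivity on the undirected projection.
    """
    if net.n_nodes < 2:
        raise ValueError("centralities are undefined for fewer than 2 nodes")
    und = net.undirected()
    closeness = nx.closeness_centrality(net.graph if closeness_directed else und)
    betweenness = nx.betweenness_centrality(
        net.graph if betweenness_directed else und, normalized=True)
    clustering = nx.clustering(und)
    nodes = sorted(net.graph.nodes)
    return pd.DataFrame(
        {
            "closeness": [closeness[i] for i in nodes],
            "betweenness": [betweenness[i] for i in nodes],
            "clustering": [clustering[i] for i in nodes],
        },
        index=pd.Index(nodes, name="ant_id"),
    )


def lorenz_gini(counts: Sequence[float]) -> tuple[np.ndarray, float]:
    """Lorenz curve and Gini coefficient of per-ant activity counts.

    Counts are sorted ascending; the Lorenz polygon runs from (0, 0) to
    (1, 1) through the cumulative activity shares.  The Gini coefficient is
    1 - 2 * (trapezoid area under the polygon), ranging from 0 (all ants
    equally active) to 1 - 1/N (a single ant does everything).

    Returns ``(points, gini)`` with ``points`` an (N+1, 2) array of Lorenz
    vertices.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1 or c.size == 0:
        raise ValueError("counts must be a nonempty 1-d sequence")
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    total = c.sum()
    if total == 0:
        raise ValueError("Gini is undefined when all counts are zero")
    y = np.concatenate([[0.0], np.cumsum(np.sort(c)) / total])
    x = np.linspace(0.0, 1.0, c.size + 1)
    area = np.trapezoid(y, x)
    return np.column_stack([x, y]), float(1.0 - 2.0 * area)


def t50(events: Iterable, horizon: Optional[int] = None) -> int:
    """Earliest timestep by which half of all event starts have occurred.

    ``horizon`` optionally restricts attention to events starting at or
    before that timestep.
    """
    starts = np.sort(np.asarray([ev.t_start for ev in events], dtype=np.int64))
    if horizon is not None:
        starts = starts[starts <= horizon]
    if starts.size == 0:
        raise ValueError("T50 is undefined for an empty event log")
    return int(starts[int(np.ceil(starts.size / 2.0)) - 1])


@dataclass
class ActivityProfile:
    """Per-ant donation/reception counts with caste labels."""

    table: pd.DataFrame  # index ant_id; columns: caste, given, received, total

    def histogram(self, column: str = "total", caste: Optional[Caste] = None) -> pd.Series:
        """Distribution of per-ant counts (zero-activity ants included)."""
        t = self.table if caste is None else self.table[self.table["caste"] == caste.value]
        return t[column].value_counts().sort_index()


def activity_distributions(events: Iterable, roster: Sequence[int],
                           caste_labels: Mapping[int, Caste]) -> ActivityProfile:
    """Count events given/received per ant, split by (final) caste.

    The five distributions analysed downstream -- all events per ant, and
    given/received per caste -- are views of the returned table; inactive
    individuals appear with zero counts.
    """
    idx = [int(i) for i in roster]
    given = {i: 0 for i in idx}
    received = {i: 0 for i in idx}
    for ev in events:
        d, r = int(ev.donor_id), int(ev.receiver_id)
        if d not in given or r not in received:
            raise ValueError(f"event references ant(s) {d}->{r} missing from the roster")
        given[d] += 1
        received[r] += 1
    table = pd.DataFrame(
        {
            "caste": [caste_labels[i].value for i in idx],
            "given": [given[i] for i in idx],
            "received": [received[i] for i in idx],
        },
        index=pd.Index(idx, name="ant_id"),
    )
    table["total"] = table["given"] + table["received"]
    return ActivityProfile(table=table)
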