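"""Node and bridge centrality for weighted symptom networks.

Conventions: strength is the sum of absolute edge weights; expected
influence the signed sum; shortest-path metrics use edge length
1/|weight|; betweenness counts unordered pairs excluding endpoints with
fractional credit for ties; closeness is the unnormalized inverse total
distance to reachable nodes (computed within the node's component, zero
for isolates).  Bridge metrics restrict the sums to edges leaving the
node's community.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from .ggm import NetworkModel

CENTRALITY_COLUMNS = [
    "strength",
    "betweenness",
    "closeness",
    "expected_influence",
]
BRIDGE_COLUMNS = ["bridge_strength", "bridge_expected_influence"]


def node_strength(net: NetworkModel) -> pd.Series:
    return pd.Series(np.abs(net.weights).sum(axis=1), index=net.labels, name="strength")


def expected_influence(net: NetworkModel) -> pd.Series:
    return pd.Series(net.weights.sum(axis=1), index=net.labels, name="expected_influence")


def _graph(net: NetworkModel) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(net.labels)
    p = net.n_nodes
    for i in range(p):
        for j in range(i + 1, p):
            w = net.weights[i, j]
            if w != 0:
                G.add_edge(net.labels[i], net.labels[j], length=1.0 / abs(w))
    return G


def betweenness_closeness(net: NetworkModel) -> pd.DataFrame:
    """Betweenness and (unnormalized) closeness over 1/|w| path lengths."""
    G = _graph(net)
    bet = nx.betweenness_centrality(G, weight="length", normalized=False)
    clo = {}
    disconnected = False
    for node in net.labels:
        dists = nx.single_source_dijkstra_path_length(G, node, weight="length")
        total = sum(d for t, d in dists.items() if t != node)
        if len(dists) < net.n_nodes:
            disconnected = True
        clo[node] = 1.0 / total if total > 0 else 0.0
    out = pd.DataFrame({"betweenness": pd.Series(bet), "closeness": pd.Series(clo)})
    out = out.loc[net.labels]
    out.attrs["disconnected"] = disconnected
    return out


def bridge_centrality(net: NetworkModel) -> pd.DataFrame:
    """Bridge strength (sum of |w| to other communities) and bridge
    expected influence (signed analog) for every node."""
    if not net.communities:
        raise ValueError("bridge centrality requires community labels")
    comm = np.array([net.communities[l] for l in net.labels])
    if len(set(comm)) < 2:
        raise ValueError("bridge centrality requires at least 2 communities")
    cross = comm[:, None] != comm[None, :]
    W = net.weights
    return pd.DataFrame(
        {
            "bridge_strength": (np.abs(W) * cross).sum(axis=1),
            "bridge_expected_influence": (W * cross).sum(axis=1),
        },
        index=net.labels,
    )


def centrality_table(net: NetworkModel, zscore: bool = False) -> pd.DataFrame:
    """Full per-node centrality table; bridge columns are included when the
    model carries >= 2 communities.  ``zscore`` appends standardized
    columns (suffix ``_z``) for plotting; raw values remain canonical."""
    out = pd.DataFrame(
        {
            "strength": node_strength(net),
            "expected_influence": expected_influence(net),
        }
    )
    bc = betweenness_closeness(net)
    out["betweenness"] = bc["betweenness"]
    out["closeness"] = bc["closeness"]
    if net.communities and len(set(net.communities.values())) >= 2:
        out = out.join(bridge_centrality(net))
    if zscore:
        for col in list(out.columns):
            sd = out[col].std(ddof=1)
            out[col + "_z"] = (out[col] - out[col].mean()) / sd if sd > 0 else 0.0
    return out
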