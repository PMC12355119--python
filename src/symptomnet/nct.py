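"""Permutation network comparison test (NCT) for two groups.

Both group networks are re-estimated (correlations + EBIC-glasso) on
each of K permutations of the pooled respondents, preserving the
original group sizes.  Test statistics: S, the absolute difference in
global strength (signed "expected influence" variant by default, i.e.
the plain sum of edge weights), and M, the maximum absolute edge-weight
difference (network structure invariance).  Optional per-edge and
per-node-centrality invariance tests reuse the same permutation draws;
edge p-values are Holm-corrected.  All p-values use the add-one
convention p = (1 + #{perm >= obs}) / (K + 1), so they are never 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .centrality import bridge_centrality, expected_influence, node_strength
from .ggm import NetworkModel, estimate_network


def global_strength(net: NetworkModel, signed: bool = False) -> float:
    """Sum of upper-triangle edge weights (signed) or absolute weights."""
    iu = np.triu_indices(net.n_nodes, 1)
    w = net.weights[iu]
    return float(w.sum()) if signed else float(np.abs(w).sum())


def _centralities(net: NetworkModel, indices: tuple[str, ...]) -> np.ndarray:
    cols = []
    for index in indices:
        if index == "strength":
            cols.append(node_strength(net).to_numpy())
        elif index == "expected_influence":
            cols.append(expected_influence(net).to_numpy())
        elif index == "bridge_strength":
            cols.append(bridge_centrality(net)["bridge_strength"].to_numpy())
        elif index == "bridge_expected_influence":
            cols.append(bridge_centrality(net)["bridge_expected_influence"].to_numpy())
        else:
            raise ValueError(f"unknown centrality index {index!r}")
    return np.column_stack(cols)


@dataclass
class NctResult:
    labels: list[str]
    global_strength_a: float
    global_strength_b: float
    S: float
    p_S: float
    M: float
    p_M: float
    edge_differences: pd.DataFrame | None = None
    centrality_differences: pd.DataFrame | None = None
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "global_strength": {"a": self.global_strength_a, "b": self.global_strength_b},
            "S": self.S, "p_S": self.p_S, "M": self.M, "p_M": self.p_M,
            "settings": self.settings,
        }
        if self.edge_differences is not None:
            out["edges"] = self.edge_differences.to_dict(orient="records")
        if self.centrality_differences is not None:
            out["centrality"] = self.centrality_differences.reset_index().to_dict(orient="records")
        return out


def nct(
    data_a: pd.DataFrame,
    data_b: pd.DataFrame,
    K: int = 1000,
    seed: int = 0,
    tests: tuple[str, ...] = ("global", "structure"),
    signed_global: bool = True,
    centrality_indices: tuple[str, ...] = ("strength",),
    communities: dict[str, int] | None = None,
    **estimator_kwargs,
) -> NctResult:
    """Two-group permutation network comparison.

    ``tests`` may additionally include "edges" and "centrality"; the
    centrality invariance test defaults to strength (add
    bridge_* indices when community labels are supplied).
    """
    if list(data_a.columns) != list(data_b.columns):
        raise ValueError("both groups must share the same node set and order")
    if K < 100:
        raise ValueError("K must be >= 100")
    ekw = dict(method="auto", gamma=0.5, n_lambdas=100, lambda_min_ratio=0.01)
    ekw.update(estimator_kwargs)
    n_a, n_b = len(data_a), len(data_b)
    p = data_a.shape[1]
    if min(n_a, n_b) < p:
        import warnings

        warnings.warn("group size below node count; NCT estimates will be unstable")

    def fit(df: pd.DataFrame) -> NetworkModel:
        return estimate_network(df, communities=communities, **ekw)

    net_a, net_b = fit(data_a), fit(data_b)
    gs_a = global_strength(net_a, signed=signed_global)
    gs_b = global_strength(net_b, signed=signed_global)
    obs_S = abs(gs_a - gs_b)
    iu = np.triu_indices(p, 1)
    diff_obs = net_a.weights[iu] - net_b.weights[iu]
    obs_M = float(np.abs(diff_obs).max())
    do_edges = "edges" in tests
    do_cent = "centrality" in tests
    if do_cent:
        cent_obs = _centralities(net_a, centrality_indices) - _centralities(net_b, centrality_indices)

    pooled = pd.concat([data_a, data_b], ignore_index=True)
    rng = np.random.default_rng(seed)
    ge_S = ge_M = 0
    edge_ge = np.zeros(iu[0].size)
    cent_ge = np.zeros(cent_obs.shape) if do_cent else None
    for _ in range(K):
        perm = rng.permutation(n_a + n_b)
        pa = pooled.iloc[perm[:n_a]]
        pb = pooled.iloc[perm[n_a:]]
        try:
            na, nb = fit(pa), fit(pb)
        except Exception:
            perm = rng.permutation(n_a + n_b)
            na, nb = fit(pooled.iloc[perm[:n_a]]), fit(pooled.iloc[perm[n_a:]])
        S_k = abs(global_strength(na, signed=signed_global) - global_strength(nb, signed=signed_global))
        d_k = na.weights[iu] - nb.weights[iu]
        if S_k >= obs_S:
            ge_S += 1
        if np.abs(d_k).max() >= obs_M:
            ge_M += 1
        if do_edges:
            edge_ge += np.abs(d_k) >= np.abs(diff_obs)
        if do_cent:
            cent_ge += np.abs(_centralities(na, centrality_indices)
                              - _centralities(nb, centrality_indices)) >= np.abs(cent_obs)
    p_S = (1.0 + ge_S) / (K + 1.0)
    p_M = (1.0 + ge_M) / (K + 1.0)
    edge_df = None
    if do_edges:
        raw = (1.0 + edge_ge) / (K + 1.0)
        adj = np.minimum(multipletests(raw, method="holm")[1], 1.0)
        edge_df = pd.DataFrame(
            {
                "node_a": [data_a.columns[i] for i in iu[0]],
                "node_b": [data_a.columns[j] for j in iu[1]],
                "difference": diff_obs,
                "p": raw,
                "p_holm": adj,
            }
        )
    cent_df = None
    if do_cent:
        raw = (1.0 + cent_ge) / (K + 1.0)
        cent_df = pd.DataFrame(
            np.column_stack([cent_obs, raw]),
            index=list(data_a.columns),
            columns=[f"diff_{i}" for i in centrality_indices]
            + [f"p_{i}" for i in centrality_indices],
        )
    return NctResult(
        labels=list(data_a.columns),
        global_strength_a=gs_a,
        global_strength_b=gs_b,
        S=obs_S,
        p_S=p_S,
        M=obs_M,
        p_M=p_M,
        edge_differences=edge_df,
        centrality_differences=cent_df,
        settings={"K": K, "seed": seed, "signed_global": signed_global,
                  "tests": list(tests), "centrality_indices": list(centrality_indices), **ekw},
    )
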