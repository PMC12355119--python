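"""Score-based Bayesian network structure learning with bootstrap
model averaging.

Variables are treated as continuous Gaussian (the standard practice for
ordinal dimension/item scores in this literature).  The decomposable
network score is the Gaussian BIC in the higher-is-better convention:

    score(G) = sum_i [ loglik_i(parents_i) - (|parents_i| + 2)/2 * log n ]

where each local likelihood is that of a linear-Gaussian regression of
the node on its parents (parameters: coefficients, intercept, residual
variance).  Structure search is greedy hill climbing over
add/delete/reverse moves with seeded random restarts; model averaging
bootstraps the data, records per-pair presence and direction
frequencies, and retains edges that are both frequent enough and
directionally consistent (>= 75% of their appearances by default).

Reported edge strengths follow the averaging convention of score-based
arc strength: strength = score(G without edge) - score(G with edge)
on the full data, times 2 on the deviance scale — negative values mean
the edge improves fit (its inclusion lowers the lower-is-better BIC).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def local_score(X: np.ndarray, node: int, parents: tuple[int, ...], n: int,
                cache: dict | None = None) -> float:
    """Gaussian BIC local score (higher is better) of ``node`` given
    ``parents``: max log-likelihood of the linear regression minus
    (k + 2)/2 * log n for k parents."""
    key = (node, parents)
    if cache is not None and key in cache:
        return cache[key]
    y = X[:, node]
    if parents:
        A = np.column_stack([X[:, list(parents)], np.ones(n)])
        coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        if rank < A.shape[1]:  # singular design: ridge fallback
            G = A.T @ A + 1e-8 * np.eye(A.shape[1])
            coef = np.linalg.solve(G, A.T @ y)
        resid = y - A @ coef
    else:
        resid = y - y.mean()
    sigma2 = max(float(resid @ resid) / n, 1e-12)
    ll = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    sc = ll - (len(parents) + 2) / 2.0 * np.log(n)
    if cache is not None:
        cache[key] = sc
    return sc


def total_score(X: np.ndarray, parent_sets: list[tuple[int, ...]],
                cache: dict | None = None) -> float:
    n = X.shape[0]
    return sum(local_score(X, i, ps, n, cache) for i, ps in enumerate(parent_sets))


def _has_path(adj: np.ndarray, src: int, dst: int) -> bool:
    """DFS reachability src -> dst along directed edges."""
    stack = [src]
    seen = np.zeros(adj.shape[0], dtype=bool)
    while stack:
        u = stack.pop()
        if u == dst:
            return True
        if seen[u]:
            continue
        seen[u] = True
        stack.extend(np.flatnonzero(adj[u]))
    return False


def _parents(adj: np.ndarray, j: int) -> tuple[int, ...]:
    return tuple(np.flatnonzero(adj[:, j]))


def _greedy(X: np.ndarray, adj: np.ndarray, cache: dict, max_steps: int = 500) -> float:
    """In-place greedy hill climbing; returns the final score."""
    n, p = X.shape
    loc = [local_score(X, j, _parents(adj, j), n, cache) for j in range(p)]
    for _ in range(max_steps):
        best_delta, best_move = 1e-9, None
        for i in range(p):
            for j in range(p):
                if i == j:
                    continue
                if adj[i, j]:
                    # delete i -> j
                    ps = _parents(adj, j)
                    new = tuple(k for k in ps if k != i)
                    delta = local_score(X, j, new, n, cache) - loc[j]
                    if delta > best_delta:
                        best_delta, best_move = delta, ("del", i, j)
                    # reverse i -> j  (only if j -/-> i would stay acyclic)
                    adj[i, j] = False
                    ok = not _has_path(adj, i, j)
                    adj[i, j] = True
                    if ok:
                        ps_i = _parents(adj, i)
                        d = (
                            local_score(X, j, new, n, cache) - loc[j]
                            + local_score(X, i, tuple(sorted(ps_i + (j,))), n, cache) - loc[i]
                        )
                        if d > best_delta:
                            best_delta, best_move = d, ("rev", i, j)
                elif not adj[j, i]:
                    # add i -> j
                    if _has_path(adj, j, i):
                        continue
                    ps = _parents(adj, j)
                    delta = local_score(X, j, tuple(sorted(ps + (i,))), n, cache) - loc[j]
                    if delta > best_delta:
                        best_delta, best_move = delta, ("add", i, j)
        if best_move is None:
            break
        kind, i, j = best_move
        if kind == "add":
            adj[i, j] = True
        elif kind == "del":
            adj[i, j] = False
        else:
            adj[i, j] = False
            adj[j, i] = True
            loc[i] = local_score(X, i, _parents(adj, i), X.shape[0], cache)
        loc[j] = local_score(X, j, _parents(adj, j), X.shape[0], cache)
    return sum(local_score(X, j, _parents(adj, j), X.shape[0], cache) for j in range(p))


def _random_dag(p: int, rng: np.random.Generator, edge_prob: float) -> np.ndarray:
    order = rng.permutation(p)
    adj = np.zeros((p, p), dtype=bool)
    for a in range(p):
        for b in range(a + 1, p):
            if rng.random() < edge_prob:
                adj[order[a], order[b]] = True
    return adj


def hill_climb(
    data: pd.DataFrame,
    restarts: int = 10,
    seed: int = 0,
    max_steps: int = 500,
    cache: dict | None = None,
):
    """Greedy DAG search maximizing the Gaussian BIC score, with seeded
    random restarts (restart 0 starts from the empty graph).  Returns
    (adjacency bool matrix, score)."""
    X = data.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than nodes")
    if cache is None:
        cache = {}
    rng = np.random.default_rng(seed)
    best_adj, best_score = None, -np.inf
    for r in range(max(restarts, 1)):
        adj = np.zeros((p, p), dtype=bool) if r == 0 else _random_dag(p, rng, 2.0 / p)
        sc = _greedy(X, adj, cache, max_steps=max_steps)
        if sc > best_score:
            best_adj, best_score = adj.copy(), sc
    return best_adj, float(best_score)


@dataclass
class DagModel:
    nodes: list[str]
    edges: pd.DataFrame        # from, to, presence_freq, direction_freq, strength
    mbs: float
    bf: float
    bic: float
    parent_nodes: list[str]
    settings: dict = field(default_factory=dict)

    def adjacency(self) -> np.ndarray:
        idx = {l: k for k, l in enumerate(self.nodes)}
        adj = np.zeros((len(self.nodes), len(self.nodes)), dtype=bool)
        for _, row in self.edges.iterrows():
            adj[idx[row["from"]], idx[row["to"]]] = True
        return adj

    def to_dot(self, path) -> None:
        lines = ["digraph G {"]
        for nd in self.nodes:
            lines.append(f'  "{nd}";')
        for _, row in self.edges.iterrows():
            lines.append(
                f'  "{row["from"]}" -> "{row["to"]}" '
                f'[label="{row["strength"]:.2f}"];'
            )
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def dag_metrics(adj: np.ndarray, data: pd.DataFrame | None = None) -> dict:
    """Markov-blanket size (mean over nodes of |parents U children U
    co-parents|), branching factor (mean out-degree), network score on
    ``data`` (bnlearn-style: loglik minus penalty, higher is better) and
    parent nodes (roots with children)."""
    p = adj.shape[0]
    mbs = 0.0
    for i in range(p):
        blanket: set[int] = set(np.flatnonzero(adj[:, i])) | set(np.flatnonzero(adj[i]))
        for child in np.flatnonzero(adj[i]):
            blanket |= set(np.flatnonzero(adj[:, child]))
        blanket.discard(i)
        mbs += len(blanket)
    out = {
        "mbs": mbs / p,
        "bf": float(adj.sum()) / p,
        "n_edges": int(adj.sum()),
    }
    if data is not None:
        X = data.to_numpy(dtype=float)
        out["bic"] = total_score(X, [_parents(adj, j) for j in range(p)])
    roots = [
        i for i in range(p) if adj[i].any() and not adj[:, i].any()
    ]
    out["parent_node_idx"] = roots
    return out


def bootstrap_dag(
    data: pd.DataFrame,
    B: int = 200,
    presence_threshold: float = 0.5,
    direction_threshold: float = 0.75,
    restarts_per_fit: int = 2,
    seed: int = 0,
) -> DagModel:
    """Bootstrap-averaged DAG.

    Each of B nonparametric bootstrap resamples is fit by hill climbing;
    for every unordered pair the presence frequency (either direction)
    and the per-direction frequencies are recorded.  Edges with presence
    >= ``presence_threshold`` whose majority direction accounts for
    >= ``direction_threshold`` of appearances are retained in that
    direction; if the retained set contains a cycle, its lowest-presence
    edge is dropped (logged in settings) until acyclic.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    labels = list(data.columns)
    p = len(labels)
    n = len(data)
    rng = np.random.default_rng(seed)
    counts = np.zeros((p, p))                    # directed counts
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        adj, _ = hill_climb(
            data.iloc[idx], restarts=restarts_per_fit, seed=int(rng.integers(2**31))
        )
        counts += adj
    keep = np.zeros((p, p), dtype=bool)
    presence = np.zeros((p, p))
    direction = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            appear = counts[i, j] + counts[j, i]
            if appear == 0:
                continue
            pres = appear / B
            a, bnode = (i, j) if counts[i, j] >= counts[j, i] else (j, i)
            dirfreq = counts[a, bnode] / appear
            presence[a, bnode] = pres
            direction[a, bnode] = dirfreq
            if pres >= presence_threshold and dirfreq >= direction_threshold:
                keep[a, bnode] = True
    dropped = []
    import networkx as nx

    while True:
        G = nx.DiGraph(keep)
        try:
            cycle = nx.find_cycle(G)
        except nx.NetworkXNoCycle:
            break
        worst = min(cycle, key=lambda e: presence[e[0], e[1]])
        keep[worst[0], worst[1]] = False
        dropped.append((labels[worst[0]], labels[worst[1]]))

    X = data.to_numpy(dtype=float)
    cache: dict = {}
    parent_sets = [_parents(keep, j) for j in range(p)]
    full_score = total_score(X, parent_sets, cache)
    rows = []
    for i in range(p):
        for j in range(p):
            if not keep[i, j]:
                continue
            ps = parent_sets[j]
            without = tuple(k for k in ps if k != i)
            delta = local_score(X, j, without, n, cache) - local_score(X, j, ps, n, cache)
            # deviance scale: negative when the edge improves fit
            rows.append(
                {
                    "from": labels[i],
                    "to": labels[j],
                    "presence_freq": presence[i, j],
                    "direction_freq": direction[i, j],
                    "strength": 2.0 * delta,
                }
            )
    edges = pd.DataFrame(rows, columns=["from", "to", "presence_freq", "direction_freq", "strength"])
    met = dag_metrics(keep, data)
    return DagModel(
        nodes=labels,
        edges=edges,
        mbs=met["mbs"],
        bf=met["bf"],
        bic=met["bic"],
        parent_nodes=[labels[i] for i in met["parent_node_idx"]],
        settings={
            "B": B,
            "presence_threshold": presence_threshold,
            "direction_threshold": direction_threshold,
            "restarts_per_fit": restarts_per_fit,
            "seed": seed,
            "dropped_for_acyclicity": dropped,
        },
    )
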