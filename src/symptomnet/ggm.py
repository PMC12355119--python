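"""Regularized partial-correlation network estimation.

The network is a Gaussian graphical model: nodes are symptoms, edges are
partial correlations of the selected sparse inverse-covariance matrix.
Estimation fits a graphical-lasso path and selects the penalty by the
Extended Bayesian Information Criterion (EBIC),

    EBIC(lambda) = -2 loglik(K_lambda) + E log n + 4 E gamma log p,

with E the number of selected edges and gamma the hyperprior on sparsity
(default 0.5).  The log-likelihood uses the penalized estimate itself,
matching the convention of the reference EBIC-glasso implementations; a
refit-based likelihood would shift selection slightly.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlations import CorrelationMatrix

_SUPPORT_TOL = 1e-8


@dataclass
class NetworkModel:
    """Symmetric weighted partial-correlation network over labelled nodes."""

    labels: list[str]
    weights: np.ndarray
    communities: dict[str, int] = field(default_factory=dict)
    lambda_selected: float = float("nan")
    n: int = 0
    gamma: float = float("nan")

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.shape != (len(self.labels), len(self.labels)):
            raise ValueError("weight matrix shape mismatch")
        if not np.allclose(W, W.T, atol=1e-8):
            raise ValueError("weights must be symmetric")
        if np.abs(np.diag(W)).max(initial=0.0) > 1e-10:
            raise ValueError("weights must have zero diagonal")
        if np.abs(W).max(initial=0.0) > 1.0 + 1e-8:
            raise ValueError("partial correlations must lie in [-1, 1]")
        self.weights = W

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def edge_list(self) -> pd.DataFrame:
        rows = []
        p = self.n_nodes
        for i in range(p):
            for j in range(i + 1, p):
                if abs(self.weights[i, j]) > 0:
                    rows.append((self.labels[i], self.labels[j], self.weights[i, j]))
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])

    def to_json(self, path=None) -> str:
        payload = {
            "labels": self.labels,
            "weights": self.weights.tolist(),
            "communities": self.communities,
            "lambda_selected": self.lambda_selected,
            "n": self.n,
            "gamma": self.gamma,
        }
        s = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, path) -> "NetworkModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            labels=payload["labels"],
            weights=np.array(payload["weights"]),
            communities=payload.get("communities", {}),
            lambda_selected=payload.get("lambda_selected", float("nan")),
            n=payload.get("n", 0),
            gamma=payload.get("gamma", float("nan")),
        )

    def to_graphml(self, path) -> None:
        import networkx as nx

        G = nx.Graph()
        for lab in self.labels:
            G.add_node(lab, community=self.communities.get(lab, 0))
        for _, row in self.edge_list().iterrows():
            G.add_edge(row.node_a, row.node_b, weight=float(row.weight))
        nx.write_graphml(G, path)


def _glasso_cd(
    S: np.ndarray,
    lam: float,
    W: np.ndarray,
    B: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Blockwise coordinate-descent graphical lasso (Friedman et al. style),
    off-diagonal penalty only.  ``W`` (working covariance) and ``B``
    (nodewise regression coefficients) are modified in place, which lets a
    lambda path warm-start each fit from the previous solution."""
    p = S.shape[0]
    off_scale = np.abs(S - np.diag(np.diag(S))).mean() + 1e-12
    converged = False
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            idx = np.concatenate([np.arange(j), np.arange(j + 1, p)])
            W11 = W[np.ix_(idx, idx)]
            s12 = S[idx, j]
            beta = B[idx, j].copy()
            # lasso sub-problem by coordinate descent
            r = s12 - W11 @ beta
            for _ in range(max_iter):
                inner_delta = 0.0
                for k in range(p - 1):
                    old = beta[k]
                    z = r[k] + W11[k, k] * old
                    new = np.sign(z) * max(abs(z) - lam, 0.0) / W11[k, k]
                    if new != old:
                        r += W11[:, k] * (old - new)
                        beta[k] = new
                        inner_delta = max(inner_delta, abs(new - old))
                if inner_delta < tol * off_scale:
                    break
            w12 = W11 @ beta
            max_delta = max(max_delta, np.abs(W[idx, j] - w12).max(initial=0.0))
            W[idx, j] = w12
            W[j, idx] = w12
            B[idx, j] = beta
        if max_delta < tol * off_scale:
            converged = True
            break
    # recover precision from (W, B)
    K = np.empty((p, p))
    for j in range(p):
        idx = np.concatenate([np.arange(j), np.arange(j + 1, p)])
        k22 = 1.0 / (W[j, j] - W[idx, j] @ B[idx, j])
        K[j, j] = k22
        K[idx, j] = -B[idx, j] * k22
    K = (K + K.T) / 2.0
    return W, K, converged


def graphical_lasso(S: np.ndarray, lam: float, max_iter: int = 200, tol: float = 1e-6) -> np.ndarray:
    """L1-penalized precision estimate maximizing
    log det K - tr(SK) - lam * sum_{i != j} |K_ij|."""
    S = np.asarray(S, dtype=float)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if lam == 0:
        return np.linalg.inv(S)
    W = S.copy().astype(float)
    B = np.zeros_like(W)
    _, K, converged = _glasso_cd(S, lam, W, B, max_iter, tol)
    if not converged:
        sign, _ = np.linalg.slogdet(K)
        if sign <= 0:
            raise RuntimeError(
                f"graphical lasso failed at lam={lam}: non-PD iterate after {max_iter} sweeps"
            )
        warnings.warn(f"graphical lasso stopped at max_iter={max_iter} for lam={lam}")
    return K


def precision_to_partial(K: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(K))
    P = -K / np.outer(d, d)
    np.fill_diagonal(P, 0.0)
    P[np.abs(P) < _SUPPORT_TOL] = 0.0
    return np.clip(P, -1.0, 1.0)


def constrained_mle(
    S: np.ndarray, support: np.ndarray, max_sweeps: int = 100, tol: float = 1e-7
) -> np.ndarray:
    """Gaussian MLE of the precision matrix under a fixed zero pattern
    (covariance selection).  Nodewise iterative-proportional-scaling
    sweeps: each column of the working covariance is replaced by its
    projection onto the node's permitted neighbours, which converges to
    the matrix matching S on the support and inverse-zero elsewhere."""
    p = S.shape[0]
    W = S.copy()
    neigh = [np.flatnonzero(support[j]) for j in range(p)]
    for _ in range(max_sweeps):
        delta = 0.0
        for j in range(p):
            N = neigh[j]
            idx = np.delete(np.arange(p), j)
            if N.size == 0:
                new_col = np.zeros(p - 1)
            else:
                beta = np.linalg.solve(W[np.ix_(N, N)], S[N, j])
                new_col = W[np.ix_(idx, N)] @ beta
            delta = max(delta, np.abs(W[idx, j] - new_col).max(initial=0.0))
            W[idx, j] = new_col
            W[j, idx] = new_col
        if delta < tol:
            break
    K = np.linalg.inv(W)
    # clean numerically-zero entries off the support
    K[(~support) & ~np.eye(p, dtype=bool)] = 0.0
    return (K + K.T) / 2.0


def gaussian_loglik(S: np.ndarray, K: np.ndarray, n: int) -> float:
    """Multivariate-normal log-likelihood of the sample at precision K."""
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        return -np.inf
    return 0.5 * n * (logdet - np.trace(S @ K) - p * np.log(2.0 * np.pi))


def ebic(S: np.ndarray, K: np.ndarray, n: int, gamma: float) -> float:
    p = S.shape[0]
    E = int(np.count_nonzero(np.abs(np.triu(K, 1)) > _SUPPORT_TOL))
    return -2.0 * gaussian_loglik(S, K, n) + E * np.log(n) + 4.0 * E * gamma * np.log(p)


def lambda_path(S: np.ndarray, n_lambdas: int = 100, lambda_min_ratio: float = 0.01) -> np.ndarray:
    lam_max = np.abs(S - np.diag(np.diag(S))).max()
    if lam_max <= 0:
        lam_max = 1e-3
    return np.logspace(np.log10(lam_max), np.log10(lam_max * lambda_min_ratio), n_lambdas)


def ebic_select(
    S: CorrelationMatrix | np.ndarray,
    n: int,
    gamma: float = 0.5,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 0.01,
    refit: bool = True,
    labels: list[str] | None = None,
    communities: dict[str, int] | None = None,
) -> NetworkModel:
    """Fit the graphical-lasso path and return the EBIC-minimizing network,
    with precision entries converted to partial correlations.

    With ``refit=True`` (default) the likelihood entering EBIC is that of
    the support-constrained MLE for each candidate sparsity pattern, and
    the selected model's weights are the refit partial correlations.
    With ``refit=False`` the penalized estimates are scored and returned
    directly; this alternative convention conflates shrinkage bias with
    model complexity and selects substantially denser networks.
    """
    if isinstance(S, CorrelationMatrix):
        labels = labels or S.labels
        S = S.values
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if labels is None:
        labels = [f"V{i + 1}" for i in range(p)]
    if n <= p:
        warnings.warn(f"sample size {n} <= node count {p}; estimates will be unstable")
    lams = lambda_path(S, n_lambdas, lambda_min_ratio)
    if lams.size == 0:
        raise ValueError("empty lambda path")
    best = None
    failures = 0
    seen_supports: dict[bytes, float] = {}
    W = S.copy()
    B = np.zeros_like(S)
    for lam in lams:
        try:
            # warm-started path: W and B carry over between penalties
            W, K_pen, _ = _glasso_cd(S, float(lam), W, B, max_iter=200, tol=1e-6)
        except (RuntimeError, np.linalg.LinAlgError, FloatingPointError):
            failures += 1
            W = S.copy()
            B = np.zeros_like(S)
            continue
        support = np.abs(K_pen) > _SUPPORT_TOL
        np.fill_diagonal(support, False)
        if refit:
            key = np.packbits(support).tobytes()
            if key in seen_supports:
                continue
            try:
                K = constrained_mle(S, support)
            except np.linalg.LinAlgError:
                failures += 1
                continue
            seen_supports[key] = float(lam)
        else:
            K = K_pen
        crit = ebic(S, K, n, gamma)
        if best is None or crit < best[0]:
            best = (crit, float(lam), K)
    if best is None:
        raise RuntimeError(f"all {failures} lambda-path fits failed")
    _, lam_sel, K_sel = best
    return NetworkModel(
        labels=list(labels),
        weights=precision_to_partial(K_sel),
        communities=dict(communities or {}),
        lambda_selected=lam_sel,
        n=n,
        gamma=gamma,
    )


def estimate_network(
    data: pd.DataFrame,
    method: str = "auto",
    gamma: float = 0.5,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 0.01,
    communities: dict[str, int] | None = None,
) -> NetworkModel:
    """Correlation matrix + EBIC-glasso in one step (the estimator used by
    the bootstrap, comparison and pipeline stages)."""
    from .correlations import correlation_matrix

    corr = correlation_matrix(data, method=method)
    return ebic_select(
        corr,
        n=len(data),
        gamma=gamma,
        n_lambdas=n_lambdas,
        lambda_min_ratio=lambda_min_ratio,
        communities=communities,
    )


def network_summary(net: NetworkModel, top_k: int = 5) -> dict:
    """Edge-count and weight summary of a fitted network.

    The mean edge weight is reported both over nonzero edges and over all
    possible edges because published summaries are often ambiguous about
    the denominator.
    """
    p = net.n_nodes
    iu = np.triu_indices(p, 1)
    w = net.weights[iu]
    n_possible = p * (p - 1) // 2
    nz = np.abs(w) > 0
    n_nonzero = int(nz.sum())
    order = np.argsort(-np.abs(w))
    strongest = [
        (net.labels[iu[0][k]], net.labels[iu[1][k]], float(w[k]))
        for k in order[:top_k]
        if abs(w[k]) > 0
    ]
    return {
        "n_nodes": p,
        "n_possible": n_possible,
        "n_nonzero": n_nonzero,
        "n_zero": n_possible - n_nonzero,
        "pct_nonzero": round(100.0 * n_nonzero / n_possible, 2),
        "pct_zero": round(100.0 * (n_possible - n_nonzero) / n_possible, 2),
        "mean_abs_weight_nonzero": float(np.abs(w[nz]).mean()) if n_nonzero else 0.0,
        "mean_abs_weight_all": float(np.abs(w).mean()),
        "strongest_edges": strongest,
    }
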