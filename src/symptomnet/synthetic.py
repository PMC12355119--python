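"""Synthetic ordinal questionnaire data with known network structure.

The generator emulates the study design the package analyses: 20 symptom
nodes in two communities (7 fear-of-recurrence dimensions, 13 pain-
catastrophizing items), 5-category Likert responses arising from a latent
multivariate Gaussian whose sparse precision matrix encodes the true
partial-correlation network, plus a handful of planted cross-community
"bridge" edges.  Every downstream stage is tested against this known
truth because the study's questionnaire data are not public.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Right-skewed default cut points: most mass in the low categories, as is
# typical for symptom ratings (cell probs ~ 0.40/0.29/0.17/0.09/0.04).
DEFAULT_THRESHOLDS = (-0.25, 0.55, 1.15, 1.75)


@dataclass
class GeneratorSpec:
    """Design of a synthetic two-community symptom network study."""

    n_nodes_per_community: tuple[int, int] = (7, 13)
    within_density: float = 0.2
    n_bridge_edges: int = 2
    weight_range: tuple[float, float] = (0.15, 0.3)
    n_categories: int = 5
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    n_respondents: int = 346
    seed: int = 0
    negative_edge_prob: float = 0.0
    min_eigenvalue: float = 0.01
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        p1, p2 = self.n_nodes_per_community
        if p1 < 1 or p2 < 1:
            raise ValueError("each community needs at least one node")
        if not 0.0 <= self.within_density <= 1.0:
            raise ValueError("within_density must be in [0, 1]")
        if self.n_bridge_edges < 0 or self.n_bridge_edges > p1 * p2:
            raise ValueError("invalid n_bridge_edges")
        lo, hi = self.weight_range
        if not 0.0 < lo <= hi:
            raise ValueError("weight_range must be a positive interval")
        if self.n_categories < 2:
            raise ValueError("need at least 2 categories")
        if list(self.thresholds) != sorted(self.thresholds) or len(
            set(self.thresholds)
        ) != len(self.thresholds):
            raise ValueError("thresholds must be strictly increasing")
        if len(self.thresholds) != self.n_categories - 1:
            raise ValueError("need n_categories - 1 thresholds")
        if not self.node_labels:
            self.node_labels = [f"F{i + 1}" for i in range(p1)] + [
                f"P{i + 1}" for i in range(p2)
            ]
        if len(self.node_labels) != p1 + p2:
            raise ValueError("node_labels length mismatch")

    @property
    def n_nodes(self) -> int:
        return sum(self.n_nodes_per_community)

    @property
    def communities(self) -> dict[str, int]:
        p1 = self.n_nodes_per_community[0]
        return {lab: (1 if i < p1 else 2) for i, lab in enumerate(self.node_labels)}


@dataclass
class NetworkTruth:
    """Ground truth of a generated network: planted edges with their realized
    partial correlations, community labels and bridge bookkeeping."""

    labels: list[str]
    precision: np.ndarray
    edges: list[tuple[int, int, float]]      # (i, j, partial correlation)
    communities: dict[str, int]
    bridge_edges: list[tuple[int, int]]
    bridge_nodes: list[str]

    @property
    def edge_set(self) -> set[tuple[int, int]]:
        return {(i, j) for i, j, _ in self.edges}

    def partial_correlations(self) -> np.ndarray:
        return precision_to_partial(self.precision)


def precision_to_partial(K: np.ndarray) -> np.ndarray:
    """partial_ij = -K_ij / sqrt(K_ii K_jj), zero diagonal."""
    d = np.sqrt(np.diag(K))
    P = -K / np.outer(d, d)
    np.fill_diagonal(P, 0.0)
    return P


def make_block_precision(spec: GeneratorSpec):
    """Build a sparse two-community precision matrix with planted within-
    community edges and ``n_bridge_edges`` cross-community bridges.

    Positive definiteness is enforced by shrinking all off-diagonals by a
    common factor until the minimum eigenvalue exceeds
    ``spec.min_eigenvalue`` (simple and reproducible); the returned truth
    records the realized partial correlations after shrinkage.
    """
    rng = np.random.default_rng(spec.seed)
    p1, p2 = spec.n_nodes_per_community
    p = p1 + p2
    K = np.eye(p)
    lo, hi = spec.weight_range

    def plant(i: int, j: int) -> None:
        w = rng.uniform(lo, hi)
        if rng.random() < spec.negative_edge_prob:
            w = -w
        K[i, j] = K[j, i] = -w  # K_ij = -w gives partial correlation +w

    within_pairs = []
    for a, b in ((0, p1), (p1, p)):
        for i in range(a, b):
            for j in range(i + 1, b):
                within_pairs.append((i, j))
    for i, j in within_pairs:
        if rng.random() < spec.within_density:
            plant(i, j)
    cross = [(i, j) for i in range(p1) for j in range(p1, p)]
    bridge_idx = rng.choice(len(cross), size=spec.n_bridge_edges, replace=False)
    bridge_edges = [cross[k] for k in sorted(bridge_idx)]
    for i, j in bridge_edges:
        plant(i, j)

    # shrink off-diagonals toward zero until comfortably positive definite
    off = K - np.diag(np.diag(K))
    shrink = 1.0
    for _ in range(200):
        Ks = np.eye(p) + shrink * off
        if np.linalg.eigvalsh(Ks).min() > spec.min_eigenvalue:
            break
        shrink *= 0.9
    else:
        raise ValueError("could not reach positive definiteness by shrinkage")
    K = np.eye(p) + shrink * off

    partial = precision_to_partial(K)
    edges = [
        (i, j, float(partial[i, j]))
        for i in range(p)
        for j in range(i + 1, p)
        if K[i, j] != 0.0
    ]
    bridge_nodes = sorted(
        {spec.node_labels[i] for e in bridge_edges for i in e},
        key=spec.node_labels.index,
    )
    return NetworkTruth(
        labels=list(spec.node_labels),
        precision=K,
        edges=edges,
        communities=spec.communities,
        bridge_edges=bridge_edges,
        bridge_nodes=bridge_nodes,
    )


def sample_ordinal(
    precision: np.ndarray,
    thresholds,
    n: int,
    seed: int,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Draw latent data from N(0, precision^-1) scaled to unit variances and
    discretize each node at its cut points into categories 0..K-1."""
    p = precision.shape[0]
    vals = np.linalg.eigvalsh(precision)
    if vals.min() <= 0:
        raise ValueError("precision matrix is not positive definite")
    cov = np.linalg.inv(precision)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    rng = np.random.default_rng(seed)
    latent = rng.multivariate_normal(np.zeros(p), corr, size=n, method="cholesky")
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.ndim == 1:
        thresholds = np.tile(thresholds, (p, 1))
    out = np.empty((n, p), dtype=int)
    for j in range(p):
        out[:, j] = np.searchsorted(thresholds[j], latent[:, j])
    if labels is None:
        labels = [f"V{j + 1}" for j in range(p)]
    return pd.DataFrame(out, columns=labels)


def generate_dataset(spec: GeneratorSpec, seed: int | None = None):
    """Convenience wrapper: build the truth and sample a respondent matrix.

    Returns (data, truth); ``seed`` overrides the sampling seed while the
    structural seed stays ``spec.seed`` so replicate draws share a truth.
    """
    truth = make_block_precision(spec)
    data = sample_ordinal(
        truth.precision,
        spec.thresholds,
        spec.n_respondents,
        spec.seed if seed is None else seed,
        labels=spec.node_labels,
    )
    return data, truth


def sample_ising(
    thresholds: np.ndarray,
    couplings: np.ndarray,
    n: int,
    burn_in: int = 500,
    thin: int = 1,
    seed: int = 0,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Single-chain Gibbs sampler for a binary Ising model with nodewise
    conditional logit(P(x_i = 1 | rest)) = tau_i + sum_j beta_ij x_j.
    Rows are collected after ``burn_in`` full sweeps, one per ``thin``
    sweeps thereafter."""
    tau = np.asarray(thresholds, dtype=float)
    B = np.asarray(couplings, dtype=float)
    p = tau.shape[0]
    if B.shape != (p, p) or not np.allclose(B, B.T) or np.abs(np.diag(B)).max() > 0:
        raise ValueError("couplings must be symmetric with zero diagonal")
    if thin < 1 or burn_in < 0:
        raise ValueError("invalid burn_in/thin")
    rng = np.random.default_rng(seed)
    state = (rng.random(p) < 0.5).astype(float)
    out = np.empty((n, p), dtype=int)
    n_sweeps = burn_in + n * thin
    u = rng.random((n_sweeps, p))
    kept = 0
    for s in range(n_sweeps):
        for i in range(p):
            logit = tau[i] + B[i] @ state
            state[i] = 1.0 if u[s, i] < 1.0 / (1.0 + np.exp(-logit)) else 0.0
        if s >= burn_in and (s - burn_in) % thin == 0:
            out[kept] = state
            kept += 1
            if kept == n:
                break
    if labels is None:
        labels = [f"V{j + 1}" for j in range(p)]
    return pd.DataFrame(out, columns=labels)
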