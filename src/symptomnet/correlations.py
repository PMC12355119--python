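"""Correlation input matrices for ordinal symptom data.

Implements the two-step polychoric estimator (thresholds from marginal
proportions, correlation by maximizing the bivariate-normal contingency
likelihood), an automatic method dispatcher mirroring the ``cor_auto``
convention (polychoric for few-level integer data, Pearson otherwise),
PSD smoothing, and the topological-overlap ("goldbricker") redundancy
screen based on dependent-correlation tests.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .bvn import bvn_cdf

RHO_BOUND = 0.999
# |z| cap standing in for +-infinity in threshold vectors; Phi(-8.3) ~ 5e-17
_ZCAP = 8.3
_MAX_POLYCHORIC_LEVELS = 7


@dataclass
class CorrelationMatrix:
    labels: list[str]
    values: np.ndarray
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def submatrix(self, labels: list[str]) -> "CorrelationMatrix":
        idx = [self.labels.index(l) for l in labels]
        return CorrelationMatrix(list(labels), self.values[np.ix_(idx, idx)], self.method)


def _ordinal_thresholds(x: np.ndarray):
    """Category codes, counts, and normal cut points from marginal
    cumulative proportions (without the +-inf sentinels)."""
    cats, counts = np.unique(x, return_counts=True)
    if len(cats) < 2:
        raise ValueError("variable is constant; correlation undefined")
    cum = np.cumsum(counts)[:-1] / x.shape[0]
    return cats, counts, np.clip(norm.ppf(cum), -_ZCAP, _ZCAP)


def _cell_probabilities(tx: np.ndarray, ty: np.ndarray, rho: float) -> np.ndarray:
    """Rectangle probabilities of the bivariate normal for the grid defined
    by the padded thresholds tx, ty."""
    ax = np.concatenate([[-_ZCAP - 1], tx, [_ZCAP + 1]])
    ay = np.concatenate([[-_ZCAP - 1], ty, [_ZCAP + 1]])
    H, K = np.meshgrid(ax, ay, indexing="ij")
    C = bvn_cdf(H, K, rho)
    return C[1:, 1:] - C[:-1, 1:] - C[1:, :-1] + C[:-1, :-1]


@dataclass
class PolychoricResult:
    rho: float
    x_thresholds: np.ndarray
    y_thresholds: np.ndarray


def polychoric_pair(x, y) -> PolychoricResult:
    """Two-step polychoric correlation of two ordinal vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    xc, _, tx = _ordinal_thresholds(x)
    yc, _, ty = _ordinal_thresholds(y)
    xi = np.searchsorted(xc, x)
    yi = np.searchsorted(yc, y)
    table = np.zeros((len(xc), len(yc)))
    np.add.at(table, (xi, yi), 1.0)

    def negloglik(rho: float) -> float:
        pr = np.clip(_cell_probabilities(tx, ty, rho), 1e-12, None)
        return -np.sum(table * np.log(pr))

    res = minimize_scalar(
        negloglik, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
        options={"xatol": 1e-6},
    )
    rho = float(res.x)
    if abs(rho) >= RHO_BOUND - 1e-4:
        rho = np.sign(rho) * RHO_BOUND
        warnings.warn("polychoric correlation at bound; clamped to +-0.999")
    return PolychoricResult(rho, tx, ty)


def nearest_psd(values: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Eigenvalue-clipped PSD projection, rescaled to unit diagonal."""
    vals, vecs = np.linalg.eigh((values + values.T) / 2.0)
    if vals.min() >= -1e-10:
        return values
    vals = np.clip(vals, eps, None)
    out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.clip(np.diag(out), 1e-12, None))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def _is_ordinal(col: np.ndarray) -> bool:
    if not np.all(np.isfinite(col)):
        return False
    if not np.all(col == np.round(col)):
        return False
    return len(np.unique(col)) <= _MAX_POLYCHORIC_LEVELS


def correlation_matrix(data: pd.DataFrame, method: str = "auto") -> CorrelationMatrix:
    """Correlation matrix of a respondent-by-item table.

    ``auto`` selects polychoric when every column is integer-valued with at
    most 7 distinct levels, Pearson otherwise.  The result is smoothed to
    the nearest PSD matrix (eigenvalue clipping, unit-diagonal rescale)
    when indefinite.
    """
    if len(data) < 3:
        raise ValueError("need at least 3 respondents")
    X = data.to_numpy(dtype=float)
    labels = list(data.columns)
    const = [labels[j] for j in range(X.shape[1]) if len(np.unique(X[:, j])) < 2]
    if const:
        raise ValueError(f"constant column(s): {const}")
    if method == "auto":
        method = "polychoric" if all(_is_ordinal(X[:, j]) for j in range(X.shape[1])) else "pearson"
    p = X.shape[1]
    if method == "polychoric":
        R = np.eye(p)
        for i in range(p):
            for j in range(i + 1, p):
                R[i, j] = R[j, i] = polychoric_pair(X[:, i], X[:, j]).rho
    elif method == "pearson":
        R = np.corrcoef(X, rowvar=False)
    elif method == "spearman":
        from scipy.stats import rankdata

        R = np.corrcoef(rankdata(X, axis=0), rowvar=False)
    else:
        raise ValueError(f"unknown method {method!r}")
    R = nearest_psd(R)
    return CorrelationMatrix(labels, R, method)


def dependent_correlation_test(r_ac: float, r_bc: float, r_ab: float, n: int) -> tuple[float, float]:
    """Two-sided test that two overlapping dependent correlations (sharing
    node c) differ, using the back-transformed-average z method: the
    Fisher-z difference is scaled by a covariance term evaluated at the
    back-transformed mean correlation.  Returns (z, p)."""
    r_ac = np.clip(r_ac, -0.9999, 0.9999)
    r_bc = np.clip(r_bc, -0.9999, 0.9999)
    z1, z2 = np.arctanh(r_ac), np.arctanh(r_bc)
    rm = np.tanh((z1 + z2) / 2.0)
    cov = (
        r_ab * (1.0 - 2.0 * rm**2) - 0.5 * rm**2 * (1.0 - 2.0 * rm**2 - r_ab**2)
    ) / (1.0 - rm**2) ** 2
    z = (z1 - z2) * np.sqrt((n - 3.0) / (2.0 - 2.0 * cov))
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class GoldbrickerResult:
    redundant_pairs: list[tuple[str, str, float]]  # (a, b, prop of differing thirds)
    suggested_drops: list[str]
    settings: dict


def goldbricker(
    data: pd.DataFrame,
    p_threshold: float = 0.05,
    proportion_threshold: float = 0.25,
    min_correlation: float = 0.50,
    method: str = "auto",
    corr: CorrelationMatrix | None = None,
) -> GoldbrickerResult:
    """Topological-overlap redundancy screen.

    A candidate pair (a, b) with |r_ab| >= ``min_correlation`` is flagged as
    redundant when fewer than ``proportion_threshold`` of the remaining
    nodes c show a significant difference between r(a, c) and r(b, c)
    (dependent-correlation test at ``p_threshold``) — i.e. the two items
    relate to the rest of the network near-identically.  For each flagged
    pair the member with the smaller mean absolute correlation to the
    other nodes is suggested for removal.
    """
    if corr is None:
        corr = correlation_matrix(data, method=method)
    R = corr.values
    labels = corr.labels
    p = len(labels)
    if p - 2 < 3:
        raise ValueError("goldbricker needs at least 3 third nodes (>= 5 nodes)")
    n = len(data)
    flagged: list[tuple[str, str, float]] = []
    drops: set[str] = set()
    for i in range(p):
        for j in range(i + 1, p):
            if abs(R[i, j]) < min_correlation:
                continue
            thirds = [k for k in range(p) if k not in (i, j)]
            n_diff = sum(
                1
                for k in thirds
                if dependent_correlation_test(R[i, k], R[j, k], R[i, j], n)[1] < p_threshold
            )
            prop = n_diff / len(thirds)
            if prop < proportion_threshold:
                flagged.append((labels[i], labels[j], prop))
                mean_i = np.mean([abs(R[i, k]) for k in thirds])
                mean_j = np.mean([abs(R[j, k]) for k in thirds])
                drops.add(labels[i] if mean_i < mean_j else labels[j])
    return GoldbrickerResult(
        redundant_pairs=flagged,
        suggested_drops=sorted(drops),
        settings={
            "p_threshold": p_threshold,
            "proportion_threshold": proportion_threshold,
            "min_correlation": min_correlation,
            "method": corr.method,
        },
    )
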