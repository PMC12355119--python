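"""Ising-model estimation and computer-simulated node interventions.

Symptoms are dichotomized (> 0 -> present).  The pairwise Ising model is
estimated by nodewise L1-penalized logistic regressions (the "eLasso"
approach): each node is regressed on all others over a penalty path, the
path point minimizing EBIC(gamma) is selected per node, and the two
directed estimates of each coupling are combined by the AND rule (both
must be nonzero; conservative) or the OR rule.  Simulated interventions
perturb one node's threshold by +-2 SD of the fitted threshold vector,
Gibbs-sample responses from the baseline and perturbed models with a
shared seed, and score each node by the change in expected total symptom
score (Delta score) and per-node prevalence.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .synthetic import sample_ising

_COEF_CAP = 30.0


def dichotomize(data: pd.DataFrame) -> pd.DataFrame:
    """Presence/absence coding: value > 0 -> 1, else 0."""
    out = (data > 0).astype(int)
    degenerate = [c for c in out.columns if out[c].nunique() < 2]
    out.attrs["degenerate_columns"] = degenerate
    return out


@dataclass
class IsingModel:
    labels: list[str]
    thresholds: np.ndarray          # tau_i
    couplings: np.ndarray           # beta_ij, symmetric, zero diagonal
    rule: str = "AND"
    gamma: float = 0.25
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        B = np.asarray(self.couplings, dtype=float)
        if not np.allclose(B, B.T, atol=1e-8) or np.abs(np.diag(B)).max(initial=0) > 0:
            raise ValueError("couplings must be symmetric with zero diagonal")
        self.couplings = B
        self.thresholds = np.asarray(self.thresholds, dtype=float)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)


def _logistic_ll(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically safe Bernoulli log-likelihood with logit eta
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_ising(
    data: pd.DataFrame,
    gamma: float = 0.25,
    rule: str = "AND",
    n_lambdas: int = 50,
    lambda_min_ratio: float = 0.01,
) -> IsingModel:
    """eLasso estimation of a binary pairwise Markov random field."""
    if rule not in ("AND", "OR"):
        raise ValueError("rule must be AND or OR")
    X = data.to_numpy(dtype=float)
    n, p = X.shape
    labels = list(data.columns)
    const = [labels[j] for j in range(p) if len(np.unique(X[:, j])) < 2]
    if const:
        raise ValueError(f"constant column(s) cannot be modelled: {const}")
    if n < 50:
        warnings.warn("fewer than 50 observations; Ising estimates will be noisy")
    W = np.zeros((p, p))                # directed nodewise estimates
    tau = np.zeros(p)
    for j in range(p):
        y = X[:, j]
        Z = np.delete(X, j, axis=1)
        lam_max = np.abs(Z.T @ (y - y.mean())).max() / n
        lams = np.logspace(np.log10(lam_max), np.log10(lam_max * lambda_min_ratio), n_lambdas)
        # intercept-only candidate (the start of the regularization path)
        p_marg = y.mean()
        icpt0 = float(np.log(p_marg / (1.0 - p_marg)))
        best = (-2.0 * _logistic_ll(y, np.full(n, icpt0)), icpt0, np.zeros(p - 1))
        for lam in lams:
            clf = LogisticRegression(
                l1_ratio=1.0, C=1.0 / (n * lam), solver="liblinear",
                intercept_scaling=100.0, max_iter=1000, tol=1e-6,
            )
            clf.fit(Z, y)
            beta = clf.coef_[0]
            eta = clf.intercept_[0] + Z @ beta
            k = int(np.count_nonzero(beta))
            crit = -2.0 * _logistic_ll(y, eta) + k * np.log(n) + 2.0 * gamma * k * np.log(p - 1)
            if crit < best[0]:
                best = (crit, clf.intercept_[0], beta)
        _, icpt, beta = best
        if np.abs(beta).max(initial=0.0) > _COEF_CAP or abs(icpt) > _COEF_CAP:
            warnings.warn(f"separation suspected for node {labels[j]}; coefficients capped")
            beta = np.clip(beta, -_COEF_CAP, _COEF_CAP)
            icpt = float(np.clip(icpt, -_COEF_CAP, _COEF_CAP))
        tau[j] = icpt
        W[j, np.arange(p) != j] = beta
    B = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            a, b = W[i, j], W[j, i]
            if rule == "AND":
                val = (a + b) / 2.0 if (a != 0 and b != 0) else 0.0
            else:
                nz = [v for v in (a, b) if v != 0]
                val = float(np.mean(nz)) if nz else 0.0
            B[i, j] = B[j, i] = val
    return IsingModel(
        labels=labels,
        thresholds=tau,
        couplings=B,
        rule=rule,
        gamma=gamma,
        settings={"n_lambdas": n_lambdas, "lambda_min_ratio": lambda_min_ratio, "n": n},
    )


def nodewise_predictability(model: IsingModel, data: pd.DataFrame) -> pd.Series:
    """Normalized classification accuracy of each node's Ising conditional:
    (accuracy - majority-class accuracy) / (1 - majority-class accuracy),
    floored at 0."""
    X = data[model.labels].to_numpy(dtype=float)
    out = {}
    for j, lab in enumerate(model.labels):
        eta = model.thresholds[j] + X @ model.couplings[j]
        pred = (eta > 0).astype(float)
        acc = float(np.mean(pred == X[:, j]))
        marg = float(max(X[:, j].mean(), 1.0 - X[:, j].mean()))
        out[lab] = 0.0 if marg >= 1.0 else max(0.0, (acc - marg) / (1.0 - marg))
    return pd.Series(out, name="r2")


@dataclass
class InterventionRow:
    node: str
    direction: str                  # attenuate | amplify
    delta_sum_score: float
    baseline_sum_score: float
    delta_prevalence: pd.Series
    settings: dict = field(default_factory=dict)


def _simulate_mean(model: IsingModel, tau: np.ndarray, n_sim: int, burn_in: int, seed: int):
    sim = sample_ising(
        tau, model.couplings, n_sim, burn_in=burn_in, seed=seed, labels=model.labels
    ).to_numpy(dtype=float)
    return sim.sum(axis=1).mean(), sim.mean(axis=0)


def simulate_intervention(
    model: IsingModel,
    node: str,
    direction: str,
    sd_multiplier: float = 2.0,
    n_sim: int = 10000,
    burn_in: int = 1000,
    seed: int = 0,
) -> InterventionRow:
    """Perturb one node's threshold by +-``sd_multiplier`` standard
    deviations of the threshold vector (amplify raises activation
    probability, attenuate lowers it) and report the change in mean total
    score and per-node prevalence against a baseline run sharing the same
    seed (common random numbers)."""
    if direction not in ("attenuate", "amplify"):
        raise ValueError("direction must be attenuate or amplify")
    j = model.labels.index(node)
    sd = float(np.std(model.thresholds, ddof=1))
    shift = sd_multiplier * sd * (1.0 if direction == "amplify" else -1.0)
    tau = model.thresholds.copy()
    tau[j] += shift
    base_score, base_prev = _simulate_mean(model, model.thresholds, n_sim, burn_in, seed)
    pert_score, pert_prev = _simulate_mean(model, tau, n_sim, burn_in, seed)
    return InterventionRow(
        node=node,
        direction=direction,
        delta_sum_score=pert_score - base_score,
        baseline_sum_score=base_score,
        delta_prevalence=pd.Series(pert_prev - base_prev, index=model.labels),
        settings={"sd_multiplier": sd_multiplier, "n_sim": n_sim,
                  "burn_in": burn_in, "seed": seed, "threshold_sd": sd},
    )


def run_all_interventions(
    model: IsingModel,
    sd_multiplier: float = 2.0,
    n_sim: int = 10000,
    burn_in: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Both interventions for every node; one baseline run per seed is
    shared across rows.  Returns a tidy table (node, direction,
    delta_score, own_prevalence_delta, baseline_score)."""
    base_score, base_prev = _simulate_mean(model, model.thresholds, n_sim, burn_in, seed)
    sd = float(np.std(model.thresholds, ddof=1))
    rows = []
    for j, node in enumerate(model.labels):
        for direction, sgn in (("amplify", 1.0), ("attenuate", -1.0)):
            tau = model.thresholds.copy()
            tau[j] += sgn * sd_multiplier * sd
            score, prev = _simulate_mean(model, tau, n_sim, burn_in, seed)
            rows.append(
                {
                    "node": node,
                    "direction": direction,
                    "delta_score": score - base_score,
                    "own_prevalence_delta": prev[j] - base_prev[j],
                    "baseline_score": base_score,
                }
            )
    return pd.DataFrame(rows)


def rank_targets(results: pd.DataFrame) -> dict:
    """Ranked intervention targets from a run_all_interventions table.

    Aggravation: descending delta_score under amplification.  Alleviation:
    ascending (most negative first) delta_score under attenuation.
    ``relative_influence`` is each node's share delta / sum |delta| within
    its direction (a reconstruction of the usual percentage display).
    """
    out = {}
    for key, direction, ascending in (
        ("aggravation", "amplify", False),
        ("alleviation", "attenuate", True),
    ):
        sub = results[results.direction == direction].copy()
        if sub.empty:
            raise ValueError(f"no {direction} rows in results")
        denom = sub.delta_score.abs().sum()
        sub["relative_influence"] = sub.delta_score / denom if denom > 0 else 0.0
        sub = sub.sort_values("delta_score", ascending=ascending, kind="mergesort")
        sub["rank"] = np.arange(1, len(sub) + 1)
        out[key] = sub.reset_index(drop=True)
    out["top_aggravation"] = out["aggravation"].iloc[0]["node"]
    out["top_alleviation"] = out["alleviation"].iloc[0]["node"]
    return out


def rank_consistency(
    model: IsingModel,
    n_replicates: int = 20,
    seed: int = 0,
    **kwargs,
) -> dict:
    """Seed-replicate consistency of the rank-1 targets: the fraction of
    replicate simulations agreeing with the modal top node per direction
    (a reconstruction of bootstrap consistency checks)."""
    rng = np.random.default_rng(seed)
    tops = {"aggravation": [], "alleviation": []}
    for _ in range(n_replicates):
        res = run_all_interventions(model, seed=int(rng.integers(2**31)), **kwargs)
        ranks = rank_targets(res)
        tops["aggravation"].append(ranks["top_aggravation"])
        tops["alleviation"].append(ranks["top_alleviation"])
    out = {}
    for key, vals in tops.items():
        modal = max(set(vals), key=vals.count)
        out[key] = {"modal_top": modal, "consistency": vals.count(modal) / n_replicates}
    return out
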