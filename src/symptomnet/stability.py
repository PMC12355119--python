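"""Edge-weight accuracy and centrality stability by resampling.

Two diagnostics: nonparametric bootstrap percentile intervals for every
edge weight, and the case-dropping correlation-stability (CS)
coefficient — the largest proportion of respondents that can be dropped
while subsample centralities still correlate >= ``cor_threshold`` (0.7)
with the full-sample ordering in at least 95% of subsamples.  CS > 0.25
is the conventional minimum, > 0.5 preferred.
"""
from __future__ import annotations

from dataclasses import dataclass, field
import math
import warnings

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .centrality import centrality_table
from .ggm import estimate_network

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.76, 0.05), 2))


def _estimator_kwargs(kw: dict) -> dict:
    out = dict(method="auto", gamma=0.5, n_lambdas=100, lambda_min_ratio=0.01)
    out.update(kw)
    return out


@dataclass
class EdgeBootstrapResult:
    edges: pd.DataFrame          # estimate, boot_mean, ci_lower, ci_upper per pair
    n_failures: int
    settings: dict


def edge_ci_bootstrap(
    data: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
    communities: dict[str, int] | None = None,
    **estimator_kwargs,
) -> EdgeBootstrapResult:
    """Percentile bootstrap CIs for all edge weights: resample respondents
    with replacement, re-estimate the full network per replicate."""
    if B < 100:
        raise ValueError("B must be >= 100")
    if B < 1000:
        warnings.warn("B < 1000 bootstrap replicates; intervals may be coarse")
    ekw = _estimator_kwargs(estimator_kwargs)
    full = estimate_network(data, communities=communities, **ekw)
    p = full.n_nodes
    iu = np.triu_indices(p, 1)
    rng = np.random.default_rng(seed)
    draws = np.full((B, iu[0].size), np.nan)
    n = len(data)
    failures = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            net = estimate_network(data.iloc[idx], **ekw)
        except Exception:
            failures += 1
            continue
        draws[b] = net.weights[iu]
    ok = ~np.isnan(draws).any(axis=1)
    if not ok.any():
        raise RuntimeError("every bootstrap replicate failed")
    draws = draws[ok]
    alpha = (1.0 - ci) / 2.0
    lo = np.quantile(draws, alpha, axis=0)
    hi = np.quantile(draws, 1.0 - alpha, axis=0)
    edges = pd.DataFrame(
        {
            "node_a": [full.labels[i] for i in iu[0]],
            "node_b": [full.labels[j] for j in iu[1]],
            "estimate": full.weights[iu],
            "boot_mean": draws.mean(axis=0),
            "ci_lower": lo,
            "ci_upper": hi,
        }
    )
    return EdgeBootstrapResult(
        edges=edges,
        n_failures=failures,
        settings={"B": B, "ci": ci, "seed": seed, **ekw},
    )


@dataclass
class CsResult:
    cs: dict[str, float]                       # per centrality index
    proportions: pd.DataFrame                  # drop level x index pass-rates
    settings: dict = field(default_factory=dict)


def cs_coefficient(
    data: pd.DataFrame,
    indices: tuple[str, ...] = ("strength",),
    drop_grid: tuple[float, ...] = DEFAULT_DROP_GRID,
    B: int = 1000,
    cor_threshold: float = 0.7,
    pass_proportion: float = 0.95,
    correlation: str = "spearman",
    seed: int = 0,
    communities: dict[str, int] | None = None,
    **estimator_kwargs,
) -> CsResult:
    """Case-dropping bootstrap CS coefficient for the given centrality
    indices.  Subsample centralities that are constant (e.g. an empty
    network) have undefined correlation and count as failures."""
    grid = sorted(drop_grid)
    if not grid or grid[0] <= 0 or grid[-1] > 0.9:
        raise ValueError("drop_grid must lie in (0, 0.9]")
    ekw = _estimator_kwargs(estimator_kwargs)
    full_net = estimate_network(data, communities=communities, **ekw)
    full_cent = centrality_table(full_net)
    for index in indices:
        if index not in full_cent.columns:
            raise ValueError(f"unknown centrality index {index!r}")
    n = len(data)
    p = full_net.n_nodes
    rng = np.random.default_rng(seed)
    rows = []
    for q in grid:
        keep = math.ceil((1.0 - q) * n)
        if keep < p + 1:
            warnings.warn(f"drop proportion {q} leaves n={keep} < nodes+1; skipped")
            continue
        passes = {index: 0 for index in indices}
        valid = 0
        for _ in range(B):
            idx = rng.choice(n, size=keep, replace=False)
            try:
                net = estimate_network(data.iloc[idx], communities=communities, **ekw)
            except Exception:
                continue
            cent = centrality_table(net)
            valid += 1
            for index in indices:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r = spearmanr(full_cent[index], cent[index]).statistic \
                        if correlation == "spearman" \
                        else np.corrcoef(full_cent[index], cent[index])[0, 1]
                if np.isfinite(r) and r >= cor_threshold:
                    passes[index] += 1
        if valid == 0:
            continue
        rows.append({"drop": q, **{i: passes[i] / valid for i in indices}})
    props = pd.DataFrame(rows).set_index("drop") if rows else pd.DataFrame()
    cs = {}
    for index in indices:
        qualifying = [q for q in props.index if props.loc[q, index] >= pass_proportion] \
            if not props.empty else []
        cs[index] = max(qualifying) if qualifying else 0.0
    return CsResult(
        cs=cs,
        proportions=props,
        settings={
            "B": B,
            "drop_grid": list(grid),
            "cor_threshold": cor_threshold,
            "pass_proportion": pass_proportion,
            "correlation": correlation,
            "seed": seed,
            **ekw,
        },
    )
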