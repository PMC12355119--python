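"""End-to-end orchestration of the symptom-network analysis.

Stage order mirrors the analysis plan: scoring (item-level input only)
-> redundancy screen -> separate community networks -> combined network
-> centrality and bridge centrality -> stability -> group comparison ->
Bayesian network -> Ising interventions.  A single global seed
deterministically derives every stage seed by fixed offsets; every
randomized stage echoes its effective settings into the report.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bayesnet import bootstrap_dag
from .centrality import centrality_table
from .correlations import goldbricker
from .ggm import estimate_network, network_summary
from .ising import dichotomize, fit_ising, nodewise_predictability, rank_targets, run_all_interventions
from .nct import nct
from .scales import handle_missing
from .stability import cs_coefficient, edge_ci_bootstrap

log = logging.getLogger("symptomnet")

STAGE_SEED_OFFSETS = {
    "bootstrap": 101,
    "cs": 202,
    "nct": 303,
    "bayesnet": 404,
    "ising": 505,
}


@dataclass
class RunConfig:
    """Everything a full run needs; serializes losslessly to YAML."""

    data_path: str = ""
    out_dir: str = "results"
    id_col: str | None = None
    group_col: str | None = None
    communities: dict[str, int] = field(default_factory=dict)
    seed: int = 0
    # stage toggles
    run_goldbricker: bool = True
    run_separate_networks: bool = True
    run_stability: bool = True
    run_nct: bool = True
    run_bayesnet: bool = True
    run_ising: bool = True
    # hyperparameters
    corr_method: str = "auto"
    gamma: float = 0.5
    n_lambdas: int = 100
    lambda_min_ratio: float = 0.01
    bootstrap_B: int = 1000
    cs_B: int = 1000
    nct_K: int = 1000
    bn_B: int = 200
    bn_restarts: int = 2
    ising_gamma: float = 0.25
    n_sim: int = 10000

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _stage_seed(config: RunConfig, stage: str) -> int:
    return config.seed + STAGE_SEED_OFFSETS[stage]


def run_all(config: RunConfig, data: pd.DataFrame | None = None) -> dict:
    """Execute the configured stages on a node-level respondent table
    (columns = network nodes, plus optional id/group columns) and write
    per-stage artifacts under ``config.out_dir``.  Returns the report
    dict (also written as report.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if data is None:
        data = pd.read_csv(config.data_path)
    report: dict = {"version": __version__, "config": asdict(config), "stages": {}}

    def stage(name):
        log.info("stage: %s", name)

    meta_cols = [c for c in (config.id_col, config.group_col) if c]
    nodes = data.drop(columns=meta_cols, errors="ignore")
    nodes, missing_report = handle_missing(nodes)
    data = data.loc[nodes.index]
    report["stages"]["missing"] = missing_report
    comm = config.communities or {
        c: (1 if c.startswith("F") else 2) for c in nodes.columns
    }
    ekw = dict(
        method=config.corr_method,
        gamma=config.gamma,
        n_lambdas=config.n_lambdas,
        lambda_min_ratio=config.lambda_min_ratio,
    )

    try:
        if config.run_goldbricker:
            stage("goldbricker")
            gb = goldbricker(nodes, method=config.corr_method)
            report["stages"]["goldbricker"] = {
                "redundant_pairs": gb.redundant_pairs,
                "suggested_drops": gb.suggested_drops,
                "settings": gb.settings,
            }

        if config.run_separate_networks:
            stage("separate networks")
            for cid in sorted(set(comm.values())):
                cols = [c for c in nodes.columns if comm[c] == cid]
                net_c = estimate_network(nodes[cols], communities={c: cid for c in cols}, **ekw)
                report["stages"][f"network_community_{cid}"] = network_summary(net_c)
                net_c.to_json(out / f"network_community_{cid}.json")

        stage("combined network")
        net = estimate_network(nodes, communities=comm, **ekw)
        report["stages"]["network_combined"] = network_summary(net)
        net.to_json(out / "network_combined.json")
        net.edge_list().to_csv(out / "edges_combined.tsv", sep="\t", index=False)

        stage("centrality")
        cent = centrality_table(net, zscore=True)
        cent.to_csv(out / "centrality.csv")
        report["stages"]["centrality"] = {
            "top_strength": cent.strength.idxmax(),
            "top_bridge_strength": cent.bridge_strength.idxmax()
            if "bridge_strength" in cent
            else None,
        }

        if config.run_stability:
            stage("stability")
            boot = edge_ci_bootstrap(
                nodes, B=config.bootstrap_B, seed=_stage_seed(config, "bootstrap"), **ekw
            )
            boot.edges.to_csv(out / "edge_bootstrap.csv", index=False)
            cs = cs_coefficient(
                nodes,
                indices=("strength", "bridge_strength"),
                B=config.cs_B,
                seed=_stage_seed(config, "cs"),
                communities=comm,
                **ekw,
            )
            report["stages"]["stability"] = {
                "cs": cs.cs,
                "bootstrap_failures": boot.n_failures,
                "settings": {"edge_B": config.bootstrap_B, "cs": cs.settings},
            }

        if config.run_nct and config.group_col:
            stage("nct")
            groups = data[config.group_col]
            levels = sorted(groups.dropna().unique())
            if len(levels) != 2:
                raise ValueError(f"group column must have 2 levels, got {levels}")
            res = nct(
                nodes[groups == levels[0]].reset_index(drop=True),
                nodes[groups == levels[1]].reset_index(drop=True),
                K=config.nct_K,
                seed=_stage_seed(config, "nct"),
                tests=("global", "structure", "edges", "centrality"),
                centrality_indices=("strength", "bridge_expected_influence"),
                communities=comm,
                **ekw,
            )
            with open(out / "nct.json", "w") as fh:
                json.dump(res.to_dict(), fh, indent=1, default=str)
            report["stages"]["nct"] = {
                "groups": [str(l) for l in levels],
                "global_strength": [res.global_strength_a, res.global_strength_b],
                "S": res.S, "p_S": res.p_S, "M": res.M, "p_M": res.p_M,
            }

        if config.run_bayesnet:
            stage("bayesian network")
            dag = bootstrap_dag(
                nodes,
                B=config.bn_B,
                restarts_per_fit=config.bn_restarts,
                seed=_stage_seed(config, "bayesnet"),
            )
            dag.edges.to_csv(out / "dag_edges.tsv", sep="\t", index=False)
            dag.to_dot(out / "dag.dot")
            report["stages"]["bayesnet"] = {
                "n_edges": len(dag.edges),
                "mbs": dag.mbs, "bf": dag.bf, "bic": dag.bic,
                "parent_nodes": dag.parent_nodes,
                "settings": dag.settings,
            }

        if config.run_ising:
            stage("ising interventions")
            binary = dichotomize(nodes)
            degenerate = binary.attrs["degenerate_columns"]
            usable = [c for c in binary.columns if c not in degenerate]
            model = fit_ising(binary[usable], gamma=config.ising_gamma)
            r2 = nodewise_predictability(model, binary[usable])
            res = run_all_interventions(
                model, n_sim=config.n_sim, seed=_stage_seed(config, "ising")
            )
            res.to_csv(out / "interventions.csv", index=False)
            ranks = rank_targets(res)
            report["stages"]["ising"] = {
                "degenerate_columns": degenerate,
                "r2": r2.round(4).to_dict(),
                "top_aggravation": ranks["top_aggravation"],
                "top_alleviation": ranks["top_alleviation"],
                "settings": {"gamma": config.ising_gamma, "n_sim": config.n_sim,
                             "seed": _stage_seed(config, "ising")},
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report
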