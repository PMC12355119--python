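"""Shared fixtures: small synthetic cohorts with known network truth."""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from symptomnet.synthetic import GeneratorSpec, generate_dataset

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def cohort_346():
    """Default-design synthetic cohort (20 nodes, two communities, n=346)."""
    data, truth = generate_dataset(GeneratorSpec(seed=11))
    return data, truth


@pytest.fixture(scope="session")
def cohort_small():
    """6-node cohort (3+3 communities) for fast estimator-level tests."""
    spec = GeneratorSpec(n_nodes_per_community=(3, 3), seed=5, n_respondents=800)
    data, truth = generate_dataset(spec)
    return data, truth


def all_dags(p: int):
    """Every DAG adjacency matrix on p nodes (feasible only for tiny p):
    enumerate each unordered pair's state (absent, ->, <-) and keep the
    acyclic ones."""
    import networkx as nx

    pairs = list(itertools.combinations(range(p), 2))
    for states in itertools.product((0, 1, 2), repeat=len(pairs)):
        adj = np.zeros((p, p), dtype=bool)
        for (i, j), s in zip(pairs, states):
            if s == 1:
                adj[i, j] = True
            elif s == 2:
                adj[j, i] = True
        if nx.is_directed_acyclic_graph(nx.DiGraph(adj)):
            yield adj


def edge_f1(net, truth) -> float:
    """F1 of the estimated edge set against the generator truth."""
    p = net.n_nodes
    est = {(i, j) for i in range(p) for j in range(i + 1, p) if net.weights[i, j] != 0}
    true = truth.edge_set
    if not est or not true:
        return 0.0
    tp = len(est & true)
    prec, rec = tp / len(est), tp / len(true)
    return 2 * prec * rec / (prec + rec) if prec + rec else 0.0
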