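"""Questionnaire scale definitions, scoring, reliability and design-stage
sample-size arithmetic.

Two instruments are modelled: the Fear of Cancer Recurrence Inventory
(FCRI; 42 items, 7 dimensions, item 13 reverse-scored) and the Pain
Catastrophizing Scale (PCS; 13 items, 3 subscales).  Both use a 0-4
Likert response format.  The FCRI dimension-to-item layout is shipped as
an editable default (contiguous blocks following the published
instrument structure) because users may hold locally adapted versions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
import yaml


@dataclass
class ScaleDefinition:
    """An instrument: ordered items, response range, reverse-scored items
    and a subscale layout."""

    name: str
    item_ids: list[str]
    item_min: int = 0
    item_max: int = 4
    reverse_items: frozenset[str] = field(default_factory=frozenset)
    subscales: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.reverse_items = frozenset(self.reverse_items)
        if self.item_min >= self.item_max:
            raise ValueError("item_min must be < item_max")
        item_set = set(self.item_ids)
        if len(item_set) != len(self.item_ids):
            raise ValueError("duplicate item ids")
        if not self.reverse_items <= item_set:
            raise ValueError("reverse items must be declared item ids")
        seen: set[str] = set()
        for sub, items in self.subscales.items():
            extra = set(items) - item_set
            if extra:
                raise ValueError(f"subscale {sub!r} references unknown items {sorted(extra)}")
            dup = seen & set(items)
            if dup:
                raise ValueError(f"items {sorted(dup)} assigned to more than one subscale")
            seen |= set(items)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @classmethod
    def from_yaml(cls, path) -> "ScaleDefinition":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            name=raw["name"],
            item_ids=list(raw["items"]),
            item_min=int(raw.get("min", 0)),
            item_max=int(raw.get("max", 4)),
            reverse_items=frozenset(raw.get("reverse", [])),
            subscales={k: list(v) for k, v in raw.get("subscales", {}).items()},
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "name": self.name,
                    "items": list(self.item_ids),
                    "min": self.item_min,
                    "max": self.item_max,
                    "reverse": sorted(self.reverse_items),
                    "subscales": {k: list(v) for k, v in self.subscales.items()},
                },
                fh,
                sort_keys=False,
            )


def fcri_definition() -> ScaleDefinition:
    """Default FCRI layout: 7 dimensions over items fcri_1..fcri_42.

    Triggers (8), Severity (9, contains the reverse-scored item 13),
    Psychological Distress (4), Functioning Impairments (6), Insight (3),
    Reassurance (3), Coping Strategies (9).  Dimension labels F1..F7
    match the node names used throughout the network analyses.
    """
    items = [f"fcri_{i}" for i in range(1, 43)]
    blocks = {
        "F1_triggers": range(1, 9),
        "F2_severity": range(9, 18),
        "F3_distress": range(18, 22),
        "F4_functioning": range(22, 28),
        "F5_insight": range(28, 31),
        "F6_reassurance": range(31, 34),
        "F7_coping": range(34, 43),
    }
    return ScaleDefinition(
        name="FCRI",
        item_ids=items,
        reverse_items=frozenset({"fcri_13"}),
        subscales={k: [f"fcri_{i}" for i in v] for k, v in blocks.items()},
    )


def pcs_definition() -> ScaleDefinition:
    """Default PCS layout: rumination (8-11), magnification (6, 7, 13),
    helplessness (1-5, 12); items scored 0-4, total 0-52."""
    items = [f"pcs_{i}" for i in range(1, 14)]
    subs = {
        "rumination": [8, 9, 10, 11],
        "magnification": [6, 7, 13],
        "helplessness": [1, 2, 3, 4, 5, 12],
    }
    return ScaleDefinition(
        name="PCS",
        item_ids=items,
        subscales={k: [f"pcs_{i}" for i in v] for k, v in subs.items()},
    )


def _validate(defn: ScaleDefinition, data: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in defn.item_ids if c not in data.columns]
    if missing_cols:
        raise KeyError(f"data lacks items {missing_cols} required by scale {defn.name}")
    sub = data[defn.item_ids]
    if sub.isna().any().any():
        raise ValueError("missing values present; run handle_missing first")
    vals = sub.to_numpy()
    if ((vals < defn.item_min) | (vals > defn.item_max)).any():
        bad = np.argwhere((vals < defn.item_min) | (vals > defn.item_max))[0]
        raise ValueError(
            f"out-of-range value at respondent {sub.index[bad[0]]!r}, "
            f"item {defn.item_ids[bad[1]]!r}"
        )
    return sub


def reverse_score(defn: ScaleDefinition, data: pd.DataFrame) -> pd.DataFrame:
    """Apply v' = max + min - v to the reverse-keyed items (an involution)."""
    out = data[defn.item_ids].copy()
    for item in defn.reverse_items:
        out[item] = defn.item_max + defn.item_min - out[item]
    return out


def score_scale(defn: ScaleDefinition, data: pd.DataFrame) -> pd.DataFrame:
    """Per-respondent subscale scores and total after reverse transformation."""
    sub = _validate(defn, data)
    rev = reverse_score(defn, sub)
    out = pd.DataFrame(index=sub.index)
    for name, items in defn.subscales.items():
        out[name] = rev[items].sum(axis=1)
    out["total"] = rev.sum(axis=1)
    return out


def cronbach_alpha(data: pd.DataFrame, items: list[str]) -> float:
    """Cronbach's alpha, raw-covariance form:
    alpha = k/(k-1) * (1 - sum(item variances) / var(total))."""
    if len(items) < 2:
        raise ValueError("alpha needs at least 2 items")
    sub = data[list(items)]
    if len(sub) < 3:
        raise ValueError("alpha needs at least 3 respondents")
    item_var = sub.var(axis=0, ddof=1)
    total_var = sub.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score has zero variance; alpha undefined")
    k = len(items)
    return k / (k - 1) * (1.0 - item_var.sum() / total_var)


def network_sample_size(n_nodes: int, attrition: float = 0.0) -> dict[str, int]:
    """Parameter-count sample-size rule for a partial-correlation network:
    one threshold parameter per node plus one pairwise parameter per node
    pair, inflated for anticipated attrition."""
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if not 0.0 <= attrition < 1.0:
        raise ValueError("attrition must be in [0, 1)")
    thr = n_nodes
    pair = n_nodes * (n_nodes - 1) // 2
    minimum = thr + pair
    required = math.ceil(minimum / (1.0 - attrition))
    return {
        "threshold_params": thr,
        "pairwise_params": pair,
        "minimum_n": minimum,
        "required_n": required,
    }


def _pct_half_up(numer: int, denom: int) -> float:
    pct = Decimal(numer) / Decimal(denom) * 100
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def handle_missing(data: pd.DataFrame, policy: str = "listwise"):
    """Missing-data handling; the only policy offered is listwise deletion
    (respondents with any missing item are dropped, mirroring the exclusion
    of incomplete questionnaires).  Returns (clean data, report)."""
    if policy != "listwise":
        raise ValueError(f"unknown missing-data policy {policy!r}")
    n_enrolled = len(data)
    keep = data.notna().all(axis=1)
    clean = data.loc[keep]
    dropped = int((~keep).sum())
    if len(clean) == 0:
        raise ValueError("all respondents dropped by listwise deletion")
    report = {
        "policy": policy,
        "enrolled": n_enrolled,
        "retained": int(keep.sum()),
        "dropped": dropped,
        "pct_dropped": _pct_half_up(dropped, n_enrolled),
        "pct_retained": _pct_half_up(n_enrolled - dropped, n_enrolled),
    }
    return clean, report
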