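"""Interpretation tables: ranked loadings, top edges, node and network summaries.

Following the study's reporting conventions, variables are ranked by their
loading (Pearson correlation with the canonical variate), the top-k or
top-fraction per sign are selected (e.g. top 20 per sign; 0.5% of 60378
edges = 302 per sign; top 5% in overlap analyses), selected edges are
summarized per node by the mean absolute loading over incident selected
edges, and nodes are assigned to the seven cortical resting-state
networks plus the subcortex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import EdgeIndex


@dataclass
class NetworkLabelMap:
    """region_id -> resting-state network label (7 cortical + subcortex)."""

    labels: dict[str, str]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "NetworkLabelMap":
        return cls(dict(zip(frame["region_id"].astype(str), frame["network_label"].astype(str))))

    def __getitem__(self, region_id: str) -> str:
        return self.labels[region_id]

    def missing(self, region_ids: list[str]) -> list[str]:
        return [r for r in region_ids if r not in self.labels]


@dataclass
class EdgeSelection:
    """Signed top-variable selection for one mode."""

    mode: int
    rule: str                  # e.g. "top_k=20" or "fraction=0.005"
    positive: pd.Series        # loading per selected id, descending
    negative: pd.Series        # ascending (most negative first)

    @property
    def ids(self) -> list[str]:
        return list(self.positive.index) + list(self.negative.index)


def rank_loadings(loadings: pd.DataFrame, mode: int) -> pd.Series:
    """Loadings of one mode sorted descending; ties broken by variable id."""
    col = f"mode{mode}"
    if col not in loadings.columns:
        raise ValueError(f"no {col} in loading table")
    s = loadings[col]
    order = sorted(s.index, key=lambda v: (-s[v], v))
    return s.loc[order]


def fraction_to_count(fraction: float, total: int) -> int:
    """Round half away from zero: 0.005 x 60378 = 301.89 -> 302."""
    return int(math.floor(fraction * total + 0.5))


def select_top(
    loadings: pd.DataFrame,
    mode: int,
    k: int | None = None,
    fraction: float | None = None,
) -> EdgeSelection:
    """Select the k (or round(fraction x total)) most positively and most
    negatively loaded variables of one mode, kept as separate signed tails."""
    if (k is None) == (fraction is None):
        raise ValueError("give exactly one of k or fraction")
    ranked = rank_loadings(loadings, mode)
    total = len(ranked)
    if fraction is not None:
        if not 0 < fraction <= 0.5:
            raise ValueError("fraction must be in (0, 0.5]")
        k_eff = fraction_to_count(fraction, total)
        rule = f"fraction={fraction:g}"
    else:
        k_eff = int(k)
        rule = f"top_k={k_eff}"
    if k_eff > total:
        raise ValueError(f"k={k_eff} exceeds variable count {total}")
    positive = ranked.iloc[:k_eff]
    negative = ranked.iloc[total - k_eff:][::-1]
    return EdgeSelection(mode, rule, positive, negative)


def summarize_by_node(selection: EdgeSelection, index: EdgeIndex) -> pd.Series:
    """Mean absolute loading per node over its incident selected edges.

    Nodes with no selected edge are absent from the output.
    """
    id_to_pair = dict(zip(index.edge_ids(), index.pairs))
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    both = pd.concat([selection.positive, selection.negative])
    for edge_id, loading in both.items():
        if edge_id not in id_to_pair:
            raise ValueError(f"edge {edge_id!r} not resolvable in the edge index")
        for node in id_to_pair[edge_id]:
            sums[node] = sums.get(node, 0.0) + abs(loading)
            counts[node] = counts.get(node, 0) + 1
    nodes = sorted(sums)
    return pd.Series(
        [sums[n] / counts[n] for n in nodes], index=nodes, name="mean_abs_loading"
    )


def attach_networks(
    node_summary: pd.Series,
    selection: EdgeSelection,
    index: EdgeIndex,
    label_map: NetworkLabelMap,
) -> tuple[pd.DataFrame, pd.Series]:
    """Label each summarized node with its network and count selected-edge
    endpoints per network.

    Returns the labelled node table (region, network, mean |loading|) and a
    per-network endpoint count whose total is 2 x the number of selected
    edges.  Raises when any node lacks a label.
    """
    missing = label_map.missing(list(node_summary.index))
    if missing:
        raise ValueError(f"regions without network labels: {missing}")
    labelled = pd.DataFrame(
        {
            "network": [label_map[r] for r in node_summary.index],
            "mean_abs_loading": node_summary.values,
        },
        index=node_summary.index,
    )
    id_to_pair = dict(zip(index.edge_ids(), index.pairs))
    counts: dict[str, int] = {}
    for edge_id in selection.ids:
        for node in id_to_pair[edge_id]:
            lab = label_map[node]
            counts[lab] = counts.get(lab, 0) + 1
    return labelled, pd.Series(counts, name="endpoint_count").sort_index()


def loading_table_tsv(loadings: pd.DataFrame, path) -> None:
    """Write the full loading table (variables x modes) as TSV."""
    loadings.to_csv(path, sep="\t", index_label="variable_id")


def edge_list_frame(selection: EdgeSelection, index: EdgeIndex) -> pd.DataFrame:
    """Selected edges as (region_i, region_j, sign, loading) rows for graph
    viewers."""
    id_to_pair = dict(zip(index.edge_ids(), index.pairs))
    rows = []
    for sign, series in (("positive", selection.positive), ("negative", selection.negative)):
        for edge_id, loading in series.items():
            a, b = id_to_pair[edge_id]
            rows.append({"region_i": a, "region_j": b, "sign": sign, "loading": loading})
    return pd.DataFrame(rows)
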