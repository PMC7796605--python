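"""Edge display rules, centrality indices and network export.

Display convention: an edge is shown when its absolute weight exceeds a
magnitude threshold (default .1 on the standardised/correlation scale) AND
it is significant at the p threshold (default .05).  Undirected networks
carry two directional p-values per edge; under the default 'or'-rule one
of the two suffices, under the 'and'-rule both are required.  Filtering is
non-destructive: every edge stays in the list with a ``displayed`` flag.

Centralities: strength = sum of absolute edge weights at a node; expected
influence = the signed sum (so nodes with negative edges are not inflated).
Directed networks distinguish incoming (row) and outgoing (column)
variants.  Autoregressive self-loops are excluded from the sums by default
(the exposed flag and the recorded policy make the convention auditable).
z-scaling standardises each index across nodes with the n-1 SD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx

from .network_estimation import BetweenNetwork, ContemporaneousNetwork, TemporalNetwork

__all__ = [
    "EdgeList",
    "display_edges",
    "centrality",
    "zscale",
    "export_network",
    "read_edgelist_csv",
]

EDGE_COLUMNS = ["from_node", "to_node", "weight", "p1", "p2", "directed", "displayed", "rule"]


@dataclass
class EdgeList:
    """Flat edge records with display flags.

    Directed edges appear once per ordered pair (from = predictor at t-1,
    to = outcome at t; self-loops included).  Undirected edges appear once
    with from < to in node order, carrying both directional p-values.
    """

    table: pd.DataFrame
    p_threshold: float
    r_threshold: float
    rule: str

    def displayed(self) -> pd.DataFrame:
        return self.table[self.table["displayed"]]

    def __len__(self) -> int:
        return len(self.table)


def _significant(p1, p2, p_threshold, rule):
    if np.isnan(p1) and np.isnan(p2):
        return False
    if np.isnan(p2):
        return p1 < p_threshold
    if rule == "or":
        return (p1 < p_threshold) or (p2 < p_threshold)
    return (p1 < p_threshold) and (p2 < p_threshold)


def display_edges(
    network: TemporalNetwork | ContemporaneousNetwork | BetweenNetwork,
    p_threshold: float = 0.05,
    r_threshold: float = 0.1,
    rule: str = "or",
) -> EdgeList:
    """Apply the magnitude-and-significance display rule to a network.

    Temporal networks use the single p-value of each directed coefficient;
    undirected networks combine their two directional p-values under
    ``rule``.  Edges with missing weights are never displayed.
    """
    if rule not in ("or", "and"):
        raise ValueError("rule must be 'or' or 'and'")
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must be in (0, 1]")
    if r_threshold < 0:
        raise ValueError("r_threshold must be >= 0")
    items = network.item_names
    rows = []
    if network.directed:
        for j in items:  # outcome
            for k in items:  # predictor
                w = network.weights.loc[j, k]
                p = network.pvalues.loc[j, k]
                shown = (
                    not np.isnan(w)
                    and abs(w) > r_threshold
                    and _significant(p, np.nan, p_threshold, rule)
                )
                rows.append((k, j, w, p, np.nan, True, shown, rule))
    else:
        for a, j in enumerate(items):
            for k in items[a + 1:]:
                w = network.weights.loc[j, k]
                p1 = network.p1.loc[j, k]
                p2 = network.p2.loc[j, k]
                shown = (
                    not np.isnan(w)
                    and abs(w) > r_threshold
                    and _significant(p1, p2, p_threshold, rule)
                )
                rows.append((j, k, w, p1, p2, False, shown, rule))
    table = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    return EdgeList(table=table, p_threshold=p_threshold, r_threshold=r_threshold, rule=rule)


def centrality(
    network: TemporalNetwork | ContemporaneousNetwork | BetweenNetwork,
    include_self_loops: bool = False,
) -> pd.DataFrame:
    """Strength and expected-influence centralities.

    Directed networks: in-strength(j) = sum_k |W[j, k]| (everything that
    predicts j), out-strength(j) = sum_k |W[k, j]|; expected-influence
    variants drop the absolute value.  Undirected networks: strength and
    expected influence over the node's row.  The self-loop policy is
    recorded in ``DataFrame.attrs``.
    """
    w = network.weights.to_numpy(dtype=float)
    if not np.all(np.isfinite(np.nan_to_num(w))):
        raise ValueError("network weights must be finite")
    w = np.nan_to_num(w)
    if not include_self_loops:
        w = w.copy()
        np.fill_diagonal(w, 0.0)
    items = network.item_names
    if network.directed:
        out = pd.DataFrame(
            {
                "in_strength": np.abs(w).sum(axis=1),
                "out_strength": np.abs(w).sum(axis=0),
                "in_expected_influence": w.sum(axis=1),
                "out_expected_influence": w.sum(axis=0),
            },
            index=pd.Index(items, name="item"),
        )
    else:
        out = pd.DataFrame(
            {
                "strength": np.abs(w).sum(axis=1),
                "expected_influence": w.sum(axis=1),
            },
            index=pd.Index(items, name="item"),
        )
    out.attrs["include_self_loops"] = include_self_loops
    return out


def zscale(table: pd.DataFrame) -> pd.DataFrame:
    """z-scale each centrality column across nodes ((x - mean) / SD, n-1 SD).

    Constant columns become all-zero and are listed in
    ``attrs['degenerate_columns']``.  Raw columns are kept; z-scaled
    columns are added with a ``z_`` prefix.
    """
    if len(table) < 2:
        raise ValueError("z-scaling needs at least 2 nodes")
    out = table.copy()
    degenerate = []
    for col in table.columns:
        sd = table[col].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            out["z_" + col] = 0.0
            degenerate.append(col)
        else:
            out["z_" + col] = (table[col] - table[col].mean()) / sd
    out.attrs.update(table.attrs)
    out.attrs["degenerate_columns"] = degenerate
    return out


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

_FORMATS = ("matrix-csv", "edgelist-csv", "graphml", "structured-document", "json")


def export_network(obj, path, format: str, node_groups: dict | None = None) -> None:
    """Write a network or edge list to disk.

    Formats: ``matrix-csv`` (labelled square weight matrix),
    ``edgelist-csv`` (flat edge records, round-trippable via
    :func:`read_edgelist_csv`), ``graphml`` (weights, display flags and
    node groups as attributes), ``structured-document``/``json`` (weights,
    SEs where available, both p-value matrices, flags).
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; supported: {', '.join(_FORMATS)}")
    if format == "matrix-csv":
        obj.weights.to_csv(path)
    elif format == "edgelist-csv":
        table = obj.table if isinstance(obj, EdgeList) else display_edges(obj).table
        table.to_csv(path, index=False)
    elif format == "graphml":
        _to_graphml(obj, path, node_groups)
    else:
        _to_json(obj, path, node_groups)


def read_edgelist_csv(path) -> pd.DataFrame:
    """Read back an ``edgelist-csv`` export (identical records)."""
    return pd.read_csv(path).reindex(columns=EDGE_COLUMNS)


def _edge_iter(obj):
    if isinstance(obj, EdgeList):
        for r in obj.table.itertuples(index=False):
            yield r.from_node, r.to_node, r.weight, bool(r.displayed)
    else:
        el = display_edges(obj)
        yield from _edge_iter(el)


def _node_order(obj):
    if isinstance(obj, EdgeList):
        seen = list(dict.fromkeys(obj.table["from_node"]).keys())
        for n in obj.table["to_node"]:
            if n not in seen:
                seen.append(n)
        return seen
    return obj.item_names


def _is_directed(obj):
    if isinstance(obj, EdgeList):
        return bool(obj.table["directed"].any())
    return obj.directed


def _to_graphml(obj, path, node_groups):
    g = nx.DiGraph() if _is_directed(obj) else nx.Graph()
    for n in _node_order(obj):
        g.add_node(n, group=(node_groups or {}).get(n, ""))
    for u, v, w, shown in _edge_iter(obj):
        if not np.isnan(w):
            g.add_edge(u, v, weight=float(w), displayed=shown)
    nx.write_graphml(g, path)


def _to_json(obj, path, node_groups):
    def mat(df):
        return None if df is None else df.where(df.notna(), None).to_dict()

    if isinstance(obj, EdgeList):
        doc = {
            "kind": "edgelist",
            "p_threshold": obj.p_threshold,
            "r_threshold": obj.r_threshold,
            "rule": obj.rule,
            "edges": obj.table.to_dict(orient="records"),
        }
    else:
        doc = {
            "kind": type(obj).__name__,
            "directed": obj.directed,
            "items": obj.item_names,
            "weights": mat(obj.weights),
            "node_groups": node_groups or {},
        }
        if isinstance(obj, TemporalNetwork):
            doc["se"] = mat(obj.se)
            doc["pvalues"] = mat(obj.pvalues)
        else:
            doc["p1"] = mat(obj.p1)
            doc["p2"] = mat(obj.p2)
            doc["sign_conflict"] = obj.sign_conflict.to_dict()
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=lambda x: None if pd.isna(x) else float(x))
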