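"""Protein–protein interaction topology and key-target selection.

Builds an undirected PPI graph from a STRING-style edge table (integer
combined scores on a 0–1000 scale, default high-confidence cutoff 700) and
ranks nodes by three centralities: degree, shortest-path betweenness
(normalized by the number of node pairs excluding the endpoint), and
closeness with the Wasserman–Faust component scaling so disconnected graphs
remain comparable. Key targets are the nodes clearing all three thresholds
simultaneously.

Shortest paths treat every edge as unit length; the confidence score gates
edge inclusion but does not weight distances.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .target_mapping import canonical_symbol

__all__ = ["load_ppi", "build_graph", "centralities", "filter_key_targets"]


def build_graph(edges: pd.DataFrame, score_min: int = 700) -> nx.Graph:
    """Build a PPI graph from a (protein1, protein2, combined_score) table.

    Keeps edges with ``combined_score >= score_min``; symmetrizes (an edge
    listed both ways collapses to one), drops self-loops, and validates the
    0–1000 score range, reporting offending row numbers.
    """
    required = {"protein1", "protein2", "combined_score"}
    missing = required - set(edges.columns)
    if missing:
        raise ValueError(f"PPI edge table is missing columns: {sorted(missing)}")
    g = nx.Graph()
    for i, row in enumerate(edges.to_dict("records")):
        try:
            score = int(row["combined_score"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {i}: non-integer combined_score {row['combined_score']!r}") from exc
        if not 0 <= score <= 1000:
            raise ValueError(f"row {i}: combined_score {score} outside 0-1000")
        u, v = canonical_symbol(row["protein1"]), canonical_symbol(row["protein2"])
        if not u or not v:
            raise ValueError(f"row {i}: empty protein symbol")
        if u == v:
            continue  # self-interactions carry no topological information
        if score < score_min:
            continue
        if g.has_edge(u, v):
            g[u][v]["combined_score"] = max(g[u][v]["combined_score"], score)
        else:
            g.add_edge(u, v, combined_score=score)
    return g


def load_ppi(path: str, score_min: int = 700) -> nx.Graph:
    """Read a STRING-dialect TSV and build the thresholded graph."""
    edges = pd.read_csv(path, sep="\t")
    return build_graph(edges, score_min=score_min)


def centralities(g: nx.Graph, nodes: Iterable[str] | None = None) -> pd.DataFrame:
    """Degree, betweenness and closeness for every node of ``g``.

    Betweenness uses pair-count normalization (2/((n−1)(n−2)) for undirected
    graphs); closeness uses the Wasserman–Faust scaling (n_c−1)/(n−1) per
    connected component. Isolated nodes (including roster nodes absent from
    the graph) get degree 0 and both centralities 0. Extra ``nodes`` may be
    supplied to report screened-but-unconnected proteins.
    """
    if nodes is not None:
        g = g.copy()
        g.add_nodes_from(canonical_symbol(s) for s in nodes)
    if g.number_of_nodes() == 0:
        return pd.DataFrame(columns=["symbol", "degree", "betweenness", "closeness"])
    bc = nx.betweenness_centrality(g, normalized=True)
    cc = nx.closeness_centrality(g, wf_improved=True)
    out = pd.DataFrame(
        {
            "symbol": list(g.nodes),
            "degree": [g.degree(n) for n in g.nodes],
            "betweenness": [bc[n] for n in g.nodes],
            "closeness": [cc[n] for n in g.nodes],
        }
    )
    return out.sort_values(
        ["degree", "symbol"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def filter_key_targets(
    records: pd.DataFrame,
    deg_min: float = 10,
    bc_min: float = 0.001,
    cc_min: float = 0.6,
) -> list[str]:
    """Symbols passing all three centrality thresholds (inclusive).

    Ordered by degree descending, ties by symbol.
    """
    if deg_min < 0 or bc_min < 0 or cc_min < 0:
        raise ValueError("centrality thresholds must be non-negative")
    passed = records.loc[
        (records["degree"] >= deg_min)
        & (records["betweenness"] >= bc_min)
        & (records["closeness"] >= cc_min)
    ]
    ordered = passed.sort_values(["degree", "symbol"], ascending=[False, True], kind="mergesort")
    return list(ordered["symbol"])
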