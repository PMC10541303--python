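"""Tripartite compound–target–pathway (C-T-P) network assembly and ranking.

Nodes live in three layers (compound, target, pathway) with layer-prefixed
ids ("cpd:", "tgt:", "pwy:") so compound names cannot collide with gene
symbols. Edges connect compounds to key targets and key targets to enriched
pathways only; a compound's degree equals its number of correlating key
targets and ranks candidate active compounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .target_mapping import canonical_symbol

__all__ = [
    "LAYERS",
    "CompoundRank",
    "assemble",
    "rank_compounds",
    "select_key_compounds",
    "export_cytoscape",
    "summarize",
]

log = logging.getLogger(__name__)

LAYERS = ("compound", "target", "pathway")
_PREFIX = {"compound": "cpd:", "target": "tgt:", "pathway": "pwy:"}


@dataclass(frozen=True)
class CompoundRank:
    compound_id: str
    degree: int
    correlating_targets: tuple[str, ...]


def _qualify(layer: str, raw_id: str) -> str:
    return _PREFIX[layer] + str(raw_id)


def assemble(
    compound_target_edges: Iterable[tuple[str, str]],
    target_pathway_edges: Iterable[tuple[str, str]],
    key_targets: Iterable[str],
    roster: dict[str, Iterable[str]] | None = None,
) -> nx.Graph:
    """Build the tripartite C-T-P graph.

    Compound–target edges whose target is not a key target are dropped (a
    warning reports the count); duplicate edges collapse. ``roster`` may
    declare nodes per layer (``{"compound": [...], ...}``) so that screened
    but unconnected nodes are still represented; by default only nodes with
    edges appear.
    """
    keys = {canonical_symbol(t) for t in key_targets}
    g = nx.Graph()
    for t in sorted(keys):
        g.add_node(_qualify("target", t), layer="target", label=t)
    if roster:
        for layer, ids in roster.items():
            if layer not in LAYERS:
                raise ValueError(f"unknown roster layer {layer!r}")
            for raw in ids:
                raw = canonical_symbol(raw) if layer == "target" else str(raw)
                g.add_node(_qualify(layer, raw), layer=layer, label=raw)
    dropped = 0
    for cpd, tgt in compound_target_edges:
        tgt = canonical_symbol(tgt)
        if tgt not in keys:
            dropped += 1
            continue
        c = _qualify("compound", str(cpd))
        g.add_node(c, layer="compound", label=str(cpd))
        g.add_edge(c, _qualify("target", tgt), interaction="compound-target")
    if dropped:
        log.warning("dropped %d compound-target edges referencing non-key targets", dropped)
    for tgt, pwy in target_pathway_edges:
        tgt = canonical_symbol(tgt)
        if tgt not in keys:
            dropped += 1
            log.warning("dropped target-pathway edge for non-key target %s", tgt)
            continue
        p = _qualify("pathway", str(pwy))
        g.add_node(p, layer="pathway", label=str(pwy))
        g.add_edge(_qualify("target", tgt), p, interaction="target-pathway")
    return g


def rank_compounds(net: nx.Graph) -> list[CompoundRank]:
    """Compounds by degree descending, ties by id ascending."""
    ranks = []
    for node, data in net.nodes(data=True):
        if data.get("layer") != "compound":
            continue
        targets = tuple(sorted(net.nodes[nb]["label"] for nb in net.neighbors(node)))
        ranks.append(CompoundRank(data["label"], len(targets), targets))
    return sorted(ranks, key=lambda r: (-r.degree, r.compound_id))


def select_key_compounds(
    ranks: Sequence[CompoundRank],
    top_k: int | None = None,
    degree_min: int | None = None,
) -> list[CompoundRank]:
    """Nominate key compounds by top-k rank or by a degree threshold.

    Exactly one of ``top_k`` / ``degree_min`` must be given. Selection is
    deterministic under ties (the rank order is already total).
    """
    if (top_k is None) == (degree_min is None):
        raise ValueError("specify exactly one of top_k or degree_min")
    if top_k is not None:
        if top_k <= 0:
            raise ValueError("top_k must be positive")
        return list(ranks[:top_k])
    return [r for r in ranks if r.degree >= degree_min]


def export_cytoscape(net: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables importable by standard network viewers.

    Nodes: (id, layer, label, degree), ordered compound → target → pathway,
    then by id. Edges: (source, target, interaction) with the source always
    the lower layer; ordered by source then target.
    """
    layer_order = {layer: i for i, layer in enumerate(LAYERS)}
    node_rows = [
        {"id": n, "layer": d["layer"], "label": d["label"], "degree": net.degree(n)}
        for n, d in net.nodes(data=True)
    ]
    nodes = pd.DataFrame(node_rows, columns=["id", "layer", "label", "degree"])
    if not nodes.empty:
        nodes = nodes.sort_values(
            ["layer", "id"],
            key=lambda s: s.map(layer_order) if s.name == "layer" else s,
            kind="mergesort",
        ).reset_index(drop=True)
    edge_rows = []
    for u, v, d in net.edges(data=True):
        if layer_order[net.nodes[u]["layer"]] > layer_order[net.nodes[v]["layer"]]:
            u, v = v, u
        edge_rows.append({"source": u, "target": v, "interaction": d.get("interaction", "")})
    edges = pd.DataFrame(edge_rows, columns=["source", "target", "interaction"])
    if not edges.empty:
        edges = edges.sort_values(["source", "target"], kind="mergesort").reset_index(drop=True)
    return nodes, edges


def summarize(net: nx.Graph) -> dict:
    """JSON-ready summary: node counts per layer, edge counts, top compounds."""
    per_layer = {layer: 0 for layer in LAYERS}
    for _, d in net.nodes(data=True):
        per_layer[d["layer"]] += 1
    edge_kinds = {"compound-target": 0, "target-pathway": 0}
    for _, _, d in net.edges(data=True):
        edge_kinds[d["interaction"]] += 1
    ranks = rank_compounds(net)
    return {
        "nodes": {**per_layer, "total": net.number_of_nodes()},
        "edges": {**edge_kinds, "total": net.number_of_edges()},
        "top_compounds": [
            {"compound_id": r.compound_id, "degree": r.degree, "targets": list(r.correlating_targets)}
            for r in ranks[:10]
        ],
    }
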