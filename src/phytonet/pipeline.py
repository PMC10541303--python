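"""End-to-end orchestration of the screening funnel.

Stages, in order: QED/OB compound screen → predicted-vs-disease target
intersection with the relevance cut → PPI topology and key-target selection
→ pathway over-representation → compound–target–pathway network assembly
and compound ranking. Every stage writes a plain TSV/JSON artifact and the
run ends with a machine-readable funnel report whose counts can all be
recomputed from the stage outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field

from . import io as pio
from .ctp_network import assemble, export_cytoscape, rank_compounds, select_key_compounds, summarize
from .drug_likeness import score_compounds, screen_compounds
from .enrichment import enrich
from .ppi_topology import build_graph, centralities, filter_key_targets
from .target_mapping import filter_by_relevance, intersect_targets

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]

log = logging.getLogger(__name__)

validate_inputs = pio.validate_inputs


class PipelineConfig(BaseModel):
    """Paths and cutoffs of one pipeline run; defaults are the screen's
    published operating point. Round-trips losslessly through JSON."""

    compounds: str
    predictions: str
    disease: str
    ppi: str
    gmt: str
    outdir: str = "phytonet_out"

    qed_cutoff: float = 0.4
    require_ob: bool = True
    qed_weights: str = "unit"
    prediction_probability_min: float | None = None
    relevance_min: float = 9.0
    ppi_score_min: int = 700
    deg_min: float = 10
    bc_min: float = 0.001
    cc_min: float = 0.6
    p_max: float = 0.05
    adjust: str | None = Field(default=None, description="None or 'BH'")
    top_pathways: int = 20
    compound_rule: str = "degree_min"
    compound_degree_min: int = 3
    compound_top_k: int = 7
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate_json(Path(path).read_text())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full funnel; returns the funnel report (also written as
    ``funnel_report.json`` in ``cfg.outdir`` beside all stage outputs)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "warnings": [], "timings_s": {}}

    def stage(name: str):
        t0 = time.perf_counter()

        def done(**counts):
            report["stages"][name] = counts
            report["timings_s"][name] = round(time.perf_counter() - t0, 4)
            log.info("stage %s: %s", name, counts)

        return done

    # 1. compound screen
    done = stage("screen")
    compounds = pio.read_compound_table(cfg.compounds)
    scored = score_compounds(compounds, weights=cfg.qed_weights)
    screened, funnel = screen_compounds(scored, qed_cutoff=cfg.qed_cutoff, require_ob=cfg.require_ob)
    pio.write_tsv(scored, outdir / "compounds_scored.tsv")
    pio.write_tsv(screened, outdir / "compounds_screened.tsv")
    done(**funnel)

    # 2. target intersection + relevance cut
    done = stage("targets")
    predictions = pio.read_predictions(cfg.predictions)
    if cfg.prediction_probability_min is not None and "prediction_probability" in predictions.columns:
        predictions = predictions.loc[predictions["prediction_probability"] >= cfg.prediction_probability_min]
    screened_ids = set(screened["compound_id"])
    predictions = predictions.loc[predictions["compound_id"].isin(screened_ids)]
    disease = pio.read_disease_genes(cfg.disease)
    venn = intersect_targets(predictions["symbol"], disease)
    potential = filter_by_relevance(venn, min_score=cfg.relevance_min)
    (outdir / "venn.json").write_text(json.dumps(venn.counts, indent=2) + "\n")
    pio.write_tsv(potential, outdir / "potential_targets.tsv")
    if not len(venn.common):
        report["warnings"].append("no common targets between predictions and disease genes")
    done(
        predicted_targets=len(venn.only_predicted) + len(venn.common),
        disease_genes=len(venn.only_disease) + len(venn.common),
        common=len(venn.common),
        potential=len(potential),
    )

    # 3. PPI topology
    done = stage("topology")
    ppi_edges = pio.read_ppi_edges(cfg.ppi)
    graph = build_graph(ppi_edges, score_min=cfg.ppi_score_min)
    potential_set = set(potential["symbol"])
    sub = graph.subgraph([n for n in graph.nodes if n in potential_set]).copy()
    cent = centralities(sub, nodes=potential_set)
    key_targets = filter_key_targets(cent, deg_min=cfg.deg_min, bc_min=cfg.bc_min, cc_min=cfg.cc_min)
    cent["passed_filter"] = cent["symbol"].isin(key_targets)
    pio.write_tsv(cent, outdir / "centrality.tsv")
    if not key_targets:
        report["warnings"].append("no key targets passed the topological filter")
    done(ppi_nodes=sub.number_of_nodes(), ppi_edges=sub.number_of_edges(), key_targets=len(key_targets))

    # 4. enrichment
    done = stage("enrichment")
    collection = pio.read_gmt(cfg.gmt)
    results = enrich(key_targets, collection, p_max=cfg.p_max, adjust=cfg.adjust)
    top = results.head(cfg.top_pathways)
    pio.write_tsv(results, outdir / "enrichment.tsv")
    if results.empty and key_targets:
        report["warnings"].append("no enriched terms at the significance threshold")
    done(terms_tested=len(collection), enriched=len(results), kept=len(top))

    # 5. C-T-P network
    done = stage("ctp_network")
    ct_edges = [
        (row["compound_id"], row["symbol"])
        for row in predictions.to_dict("records")
        if row["symbol"] in set(key_targets)
    ]
    tp_edges = [
        (gene, row["term_id"])
        for row in top.to_dict("records")
        for gene in str(row["genes"]).split(";")
        if gene
    ]
    net = assemble(ct_edges, tp_edges, key_targets)
    ranks = rank_compounds(net)
    if cfg.compound_rule == "degree_min":
        key_compounds = select_key_compounds(ranks, degree_min=cfg.compound_degree_min)
    else:
        key_compounds = select_key_compounds(ranks, top_k=cfg.compound_top_k)
    nodes, edges = export_cytoscape(net)
    pio.write_tsv(nodes, outdir / "ctp_nodes.tsv")
    pio.write_tsv(edges, outdir / "ctp_edges.tsv")
    ranking = pd.DataFrame(
        [
            {"compound_id": r.compound_id, "degree": r.degree,
             "correlating_targets": ";".join(r.correlating_targets),
             "key_compound": r in key_compounds}
            for r in ranks
        ],
        columns=["compound_id", "degree", "correlating_targets", "key_compound"],
    )
    pio.write_tsv(ranking, outdir / "compound_ranking.tsv")
    summary = summarize(net)
    done(
        nodes=summary["nodes"]["total"],
        compound_nodes=summary["nodes"]["compound"],
        target_nodes=summary["nodes"]["target"],
        pathway_nodes=summary["nodes"]["pathway"],
        edges=summary["edges"]["total"],
        key_compounds=len(key_compounds),
    )

    report["key_targets"] = key_targets
    report["key_compounds"] = [r.compound_id for r in key_compounds]
    report["config"] = cfg.model_dump()
    (outdir / "funnel_report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
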