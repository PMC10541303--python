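"""Synthetic study generator for the screening pipeline.

Emulates the upstream databases the screen normally queries — a multi-herb
compound library with drug-like descriptor marginals, noisy bipartite
compound→target predictions, a disease gene list with heavy-tailed
(Pareto) relevance scores, a confidence-scored PPI subnetwork with planted
hub proteins, and pathway annotation sets with planted enriched terms — so
every stage is testable offline, including planted-truth recovery.

Construction guarantees:

* Planted hubs are wired to every other node of the PPI subnetwork and the
  background degree of non-hubs is capped, so with the generator's
  recommended thresholds exactly the planted hubs pass the triple
  (degree, betweenness, closeness) filter.
* Planted enriched terms contain a controlled fraction of the hub genes, so
  they dominate the hypergeometric ranking of the hub query.
* Same seed ⇒ byte-identical output files.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import io as pio
from .drug_likeness import score_compounds, screen_compounds
from .enrichment import GeneSet

__all__ = [
    "SynthConfig",
    "SyntheticStudy",
    "paper_shaped",
    "gen_library",
    "gen_targets_and_disease",
    "gen_ppi",
    "gen_pathways",
    "generate_fixture",
]


class SynthConfig(BaseModel):
    """Knobs of the synthetic study; defaults mirror the source screen's scale."""

    seed: int = 0
    n_herbs: int = Field(default=10, ge=1)
    compounds_per_herb: int = Field(default=242, ge=0)
    n_compounds: int | None = Field(default=2419, ge=0, description="optional total-row cap")
    duplicate_rate: float = Field(default=0.91, ge=0.0, le=1.0)
    n_targets_universe: int = Field(default=3000, ge=1)
    predictions_per_compound: float = Field(default=8.0, ge=0.0)
    n_disease_genes: int = Field(default=196, ge=0)
    relevance_shape: float = Field(default=1.0, gt=0.0, description="Pareto tail index")
    relevance_frac_high: float = Field(
        default=0.4, gt=0.0, lt=1.0,
        description="target fraction of disease genes with relevance >= 9",
    )
    ppi_density: float = Field(default=0.1, ge=0.0, le=1.0)
    n_potential_targets: int = Field(default=22, ge=2, description="PPI subnetwork size floor")
    n_planted_hubs: int = Field(default=9, ge=0)
    hub_link_compounds: int = Field(default=3, ge=1, description="screened compounds force-linked per hub")
    n_key_compound_pool: int = Field(
        default=7, ge=1,
        description="size of the screened-compound pool the hub links concentrate on",
    )
    n_pathways: int = Field(default=120, ge=0)
    pathway_size_min: int = Field(default=5, ge=1)
    pathway_size_max: int = Field(default=40, ge=1)
    n_planted_enriched_terms: int = Field(default=5, ge=0)
    planted_overlap: float = Field(default=1.0, gt=0.0, le=1.0)
    qed_cutoff: float = 0.4

    @property
    def n_rows(self) -> int:
        total = self.n_herbs * self.compounds_per_herb
        return min(total, self.n_compounds) if self.n_compounds is not None else total


def paper_shaped(seed: int = 0) -> SynthConfig:
    """Preset matching the cardinalities of the original ten-herb screen
    (2,419 library rows, 196 disease genes, 9 planted hubs, 20 pathways kept)."""
    return SynthConfig(seed=seed)


@dataclass
class SyntheticStudy:
    """All generated tables plus the planted ground truth."""

    config: SynthConfig
    compounds: pd.DataFrame
    predictions: pd.DataFrame
    disease_genes: pd.DataFrame
    ppi_edges: pd.DataFrame
    pathways: list[GeneSet]
    planted_hubs: list[str]
    planted_terms: list[str]
    potential_targets: list[str]
    recommended_thresholds: dict[str, float] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the five input files the pipeline readers accept."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "compounds": outdir / "compounds.csv",
            "predictions": outdir / "predictions.tsv",
            "disease": outdir / "disease_genes.tsv",
            "ppi": outdir / "ppi_edges.tsv",
            "gmt": outdir / "pathways.gmt",
        }
        self.compounds.to_csv(paths["compounds"], index=False, lineterminator="\n")
        pio.write_tsv(self.predictions, paths["predictions"])
        pio.write_tsv(self.disease_genes, paths["disease"])
        pio.write_tsv(self.ppi_edges, paths["ppi"])
        pio.write_gmt(self.pathways, paths["gmt"])
        return paths


def _gene_universe(cfg: SynthConfig) -> list[str]:
    return [f"G{i:04d}" for i in range(1, cfg.n_targets_universe + 1)]


def _pseudo_formula(mw: float) -> str:
    # Cosmetic CHO formula of roughly the right mass; not chemically curated.
    c = max(1, int(round(mw * 0.055)))
    o = max(1, int(round(mw * 0.013)))
    h = max(1, int(round(mw - 12 * c - 16 * o)))
    return f"C{c}H{h}O{o}"


def gen_library(cfg: SynthConfig) -> pd.DataFrame:
    """Multi-herb compound descriptor table.

    Unique compounds get descriptors from drug-like marginals (lognormal MW
    around 350 g/mol, ALOGP ~ N(2.5, 1.5), Poisson counts); duplicates are
    re-emissions of an existing compound under a different herb at
    ``duplicate_rate``. The OB flag is Bernoulli conditioned on a
    Lipinski+Veber pass (0.9 vs 0.1).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n_rows = cfg.n_rows
    herbs = [f"Herb{h:02d}" for h in range(1, cfg.n_herbs + 1)]
    n_unique = max(1, int(round(n_rows * (1.0 - cfg.duplicate_rate)))) if n_rows else 0
    if n_rows == 0:
        return pd.DataFrame(columns=pio.COMPOUND_COLUMNS)

    mw = rng.lognormal(mean=math.log(350.0), sigma=0.35, size=n_unique)
    alogp = rng.normal(2.5, 1.5, size=n_unique)
    hba = rng.poisson(4.0, size=n_unique)
    hbd = rng.poisson(1.5, size=n_unique)
    psa = rng.lognormal(mean=math.log(70.0), sigma=0.5, size=n_unique)
    rotb = rng.poisson(4.0, size=n_unique)
    arom = rng.poisson(1.3, size=n_unique)
    alerts = rng.poisson(0.3, size=n_unique)
    lipinski = (mw <= 500) & (alogp <= 5) & (hbd <= 5) & (hba <= 10) & (rotb <= 10) & (psa <= 140)
    ob = np.where(lipinski, rng.random(n_unique) < 0.9, rng.random(n_unique) < 0.1)

    home_herb = rng.integers(0, cfg.n_herbs, size=n_unique)
    unique_rows = [
        {
            "compound_id": f"CMP{i + 1:05d}",
            "name": f"compound-{i + 1:05d}",
            "herbs": herbs[home_herb[i]],
            "formula": _pseudo_formula(mw[i]),
            "smiles": "",
            "mw": round(float(mw[i]), 2),
            "alogp": round(float(alogp[i]), 2),
            "hba": int(hba[i]),
            "hbd": int(hbd[i]),
            "psa": round(float(psa[i]), 2),
            "rotb": int(rotb[i]),
            "arom": int(arom[i]),
            "alerts": int(alerts[i]),
            "ob": bool(ob[i]),
        }
        for i in range(n_unique)
    ]
    rows = list(unique_rows)
    while len(rows) < n_rows:
        src = unique_rows[int(rng.integers(0, n_unique))]
        dup = dict(src)
        other = [h for h in herbs if h != src["herbs"]] or herbs
        dup["herbs"] = other[int(rng.integers(0, len(other)))]
        rows.append(dup)
    df = pd.DataFrame(rows[:n_rows], columns=pio.COMPOUND_COLUMNS)
    return df


def gen_targets_and_disease(
    cfg: SynthConfig, compound_ids: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compound→target predictions and a disease gene table.

    Per-compound target-list sizes are Poisson; targets are drawn without
    replacement with power-law popularity weights, so a few proteins are hit
    by many compounds (as real target-prediction output is). Disease
    relevance scores are Pareto with scale chosen so a score-9 cut retains
    ``relevance_frac_high`` of disease genes in expectation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    universe = np.array(_gene_universe(cfg))
    if compound_ids is None:
        compound_ids = sorted(gen_library(cfg)["compound_id"].unique())
    weights = 1.0 / np.sqrt(np.arange(1, len(universe) + 1))
    weights /= weights.sum()
    pred_rows = []
    for cid in compound_ids:
        size = min(int(rng.poisson(cfg.predictions_per_compound)), len(universe))
        if size == 0:
            continue
        symbols = rng.choice(universe, size=size, replace=False, p=weights)
        for s in sorted(symbols):
            pred_rows.append({"compound_id": cid, "symbol": s, "prediction_probability": round(float(rng.uniform(0.1, 1.0)), 3)})
    predictions = pd.DataFrame(pred_rows, columns=["compound_id", "symbol", "prediction_probability"])

    n_dis = min(cfg.n_disease_genes, len(universe))
    dis_symbols = np.sort(rng.choice(universe, size=n_dis, replace=False))
    # Pareto(shape, xm): P(X >= 9) = (xm/9)^shape == relevance_frac_high
    xm = 9.0 * cfg.relevance_frac_high ** (1.0 / cfg.relevance_shape)
    scores = xm * (1.0 - rng.random(n_dis)) ** (-1.0 / cfg.relevance_shape)
    disease = pd.DataFrame(
        {
            "symbol": dis_symbols,
            "uniprot": [f"P{zlib.crc32(s.encode()) % 100000:05d}" for s in dis_symbols],
            "relevance_score": np.round(scores, 2),
        }
    )
    return predictions, disease


@dataclass(frozen=True)
class PlantedPPI:
    edges: pd.DataFrame
    hubs: tuple[str, ...]
    thresholds: dict[str, float]


def gen_ppi(cfg: SynthConfig, nodes: list[str], hubs: list[str]) -> PlantedPPI:
    """Confidence-scored PPI edges over ``nodes`` with planted hub proteins.

    Hubs connect to every other node (degree n−1, closeness 1). Background
    (non-hub/non-hub) edges are Erdős–Rényi at ``ppi_density`` with degree
    capped below the hub degree, so the returned recommended thresholds
    separate hubs from background deterministically.
    """
    if not set(hubs) <= set(nodes):
        raise ValueError("hubs must be a subset of nodes")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    nodes = sorted(nodes)
    hub_set = set(hubs)
    non_hubs = [n for n in nodes if n not in hub_set]
    n = len(nodes)
    edges: list[tuple[str, str]] = []
    for h in sorted(hub_set):
        for other in nodes:
            if other > h or other not in hub_set:
                if other != h:
                    edges.append((min(h, other), max(h, other)))
    edges = sorted(set(edges))
    # capped background so non-hub degree stays below the recommended cutoff
    cap = max(1, int(math.floor((len(non_hubs) - 1) * cfg.ppi_density)) + 3)
    cap = min(cap, max(0, len(non_hubs) - 2))
    bg_degree = {v: 0 for v in non_hubs}
    for i, u in enumerate(non_hubs):
        for v in non_hubs[i + 1:]:
            if rng.random() < cfg.ppi_density and bg_degree[u] < cap and bg_degree[v] < cap:
                edges.append((u, v))
                bg_degree[u] += 1
                bg_degree[v] += 1
    scores = rng.integers(700, 1000, size=len(edges))
    df = pd.DataFrame(
        {
            "protein1": [e[0] for e in edges],
            "protein2": [e[1] for e in edges],
            "combined_score": scores.astype(int),
        }
    )
    deg_min = (len(hub_set) + cap + n - 1) / 2 if hub_set else 1
    thresholds = {"deg_min": float(math.ceil(deg_min)), "bc_min": 0.001 if non_hubs else 0.0, "cc_min": 0.6}
    return PlantedPPI(edges=df, hubs=tuple(sorted(hub_set)), thresholds=thresholds)


def gen_pathways(cfg: SynthConfig, key_genes: list[str]) -> tuple[list[GeneSet], list[str]]:
    """Annotation collection with ``n_planted_enriched_terms`` planted terms.

    Planted terms contain ``planted_overlap`` of the key genes plus random
    fillers; all other terms are uniform draws from the gene universe.
    Returns (collection, planted term ids).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))
    universe = np.array(_gene_universe(cfg))
    lo, hi = cfg.pathway_size_min, max(cfg.pathway_size_min, cfg.pathway_size_max)
    sets: list[GeneSet] = []
    planted_ids: list[str] = []
    n_seeded = max(1, int(round(cfg.planted_overlap * len(key_genes)))) if key_genes else 0
    for i in range(1, cfg.n_pathways + 1):
        term_id = f"PWY{i:04d}"
        size = int(rng.integers(lo, hi + 1))
        if i <= cfg.n_planted_enriched_terms and key_genes:
            seeded = list(rng.choice(np.array(sorted(key_genes)), size=min(n_seeded, len(key_genes)), replace=False))
            n_fill = max(0, size - len(seeded))
            fillers = rng.choice(universe, size=min(n_fill, len(universe)), replace=False)
            members = frozenset(seeded) | frozenset(fillers)
            planted_ids.append(term_id)
        else:
            members = frozenset(rng.choice(universe, size=min(size, len(universe)), replace=False))
        sets.append(GeneSet(term_id=term_id, term_name=f"synthetic pathway {i}", members=members, category="KEGG-like"))
    return sets, planted_ids


def generate_fixture(cfg: SynthConfig, outdir: str | Path | None = None) -> SyntheticStudy:
    """Generate one coherent study: all five inputs plus planted truth.

    The planting is anchored to the screen the pipeline will actually run:
    hub genes are force-linked to compounds that pass the QED/OB screen and
    force-listed as high-relevance disease genes, so they are guaranteed to
    reach the PPI stage; the PPI subnetwork is then built over the
    potential-target set with those hubs planted.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 5]))
    compounds = gen_library(cfg)
    predictions, disease = gen_targets_and_disease(cfg, sorted(compounds["compound_id"].unique()))

    scored = score_compounds(compounds)
    screened, _ = screen_compounds(scored, qed_cutoff=cfg.qed_cutoff, require_ob=True)
    screened_ids = sorted(screened["compound_id"])
    universe = _gene_universe(cfg)

    hubs = sorted(rng.choice(np.array(universe), size=cfg.n_planted_hubs, replace=False)) if cfg.n_planted_hubs else []
    extra_pred, extra_dis = [], []
    dis_set = set(disease["symbol"])
    # concentrate forced hub links on a small compound pool so compound-degree
    # ranking in the C-T-P network has a clear head (like real marker compounds)
    pool = (
        sorted(rng.choice(np.array(screened_ids), size=min(cfg.n_key_compound_pool, len(screened_ids)), replace=False))
        if screened_ids else []
    )
    for h in hubs:
        n_link = min(cfg.hub_link_compounds, len(pool))
        if n_link:
            for cid in rng.choice(np.array(pool), size=n_link, replace=False):
                extra_pred.append({"compound_id": cid, "symbol": h, "prediction_probability": 0.9})
        if h not in dis_set:
            extra_dis.append(
                {"symbol": h, "uniprot": f"P{zlib.crc32(h.encode()) % 100000:05d}",
                 "relevance_score": round(float(rng.uniform(12.0, 30.0)), 2)}
            )
        else:
            disease.loc[disease["symbol"] == h, "relevance_score"] = round(float(rng.uniform(12.0, 30.0)), 2)
    if extra_pred:
        predictions = pd.concat([predictions, pd.DataFrame(extra_pred)], ignore_index=True)
        predictions = predictions.drop_duplicates(["compound_id", "symbol"]).sort_values(
            ["compound_id", "symbol"], kind="mergesort").reset_index(drop=True)
    if extra_dis:
        disease = pd.concat([disease, pd.DataFrame(extra_dis)], ignore_index=True)
        disease = disease.sort_values("symbol", kind="mergesort").reset_index(drop=True)

    # potential targets as the pipeline will compute them
    pred_screened = set(predictions.loc[predictions["compound_id"].isin(screened_ids), "symbol"])
    rel = dict(zip(disease["symbol"], disease["relevance_score"]))
    potential = sorted(s for s in pred_screened & set(rel) if rel[s] >= 9.0)
    # pad the subnetwork if the random draw produced too few potential targets
    if len(potential) < cfg.n_potential_targets:
        spare = [s for s in sorted(set(rel) - set(potential)) if rel[s] >= 9.0]
        potential = sorted(set(potential) | set(spare[: cfg.n_potential_targets - len(potential)]))

    planted = gen_ppi(cfg, potential, hubs)
    pathways, planted_terms = gen_pathways(cfg, hubs)
    study = SyntheticStudy(
        config=cfg,
        compounds=compounds,
        predictions=predictions,
        disease_genes=disease,
        ppi_edges=planted.edges,
        pathways=pathways,
        planted_hubs=list(planted.hubs),
        planted_terms=planted_terms,
        potential_targets=potential,
        recommended_thresholds=planted.thresholds,
    )
    if outdir is not None:
        study.write(outdir)
    return study
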