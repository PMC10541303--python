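"""Readers, writers and validators for the pipeline's plain-text formats.

Formats: compound descriptor CSV/TSV, compound→target prediction TSV,
disease-gene TSV, STRING-dialect PPI TSV, and GMT gene-set files. All
readers validate schema and value ranges with file/row diagnostics; all
writers emit deterministic, sorted plain text.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import pandas as pd

from .enrichment import GeneSet

__all__ = [
    "COMPOUND_COLUMNS",
    "read_compound_table",
    "read_predictions",
    "read_disease_genes",
    "read_ppi_edges",
    "read_gmt",
    "write_gmt",
    "write_tsv",
    "validate_inputs",
]

COMPOUND_COLUMNS = [
    "compound_id", "name", "herbs", "formula", "smiles",
    "mw", "alogp", "hba", "hbd", "psa", "rotb", "arom", "alerts", "ob",
]

_NUMERIC_DESCRIPTORS = ["mw", "alogp", "hba", "hbd", "psa", "rotb", "arom", "alerts"]


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_compound_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a compound descriptor table (CSV or TSV)."""
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in COMPOUND_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in _NUMERIC_DESCRIPTORS:
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0])
            raise ValueError(f"{path}: missing {col} at row {row}")
    if (df["mw"] <= 0).any():
        raise ValueError(f"{path}: non-positive molecular weight")
    for col in ("hba", "hbd", "rotb", "arom", "alerts"):
        if (df[col] < 0).any() or (df[col] % 1 != 0).any():
            raise ValueError(f"{path}: column {col} must hold non-negative integers")
    if (df["psa"] < 0).any():
        raise ValueError(f"{path}: negative PSA")
    df["ob"] = df["ob"].astype(bool)
    if df["compound_id"].isna().any():
        raise ValueError(f"{path}: missing compound_id")
    return df


def read_predictions(path: str | Path) -> pd.DataFrame:
    """Read a compound→target prediction edge table (compound_id, symbol[, prediction_probability])."""
    df = pd.read_csv(path, sep="\t")
    for col in ("compound_id", "symbol"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    if "prediction_probability" in df.columns:
        bad = df["prediction_probability"].dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ValueError(f"{path}: prediction_probability outside [0, 1]")
    return df


def read_disease_genes(path: str | Path) -> pd.DataFrame:
    """Read a disease-gene table (symbol[, uniprot], relevance_score)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("symbol", "relevance_score"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    if df["relevance_score"].isna().any() or (df["relevance_score"] < 0).any():
        row = int(df.index[(df["relevance_score"].isna()) | (df["relevance_score"] < 0)][0])
        raise ValueError(f"{path}: invalid relevance_score at row {row}")
    return df


def read_ppi_edges(path: str | Path) -> pd.DataFrame:
    """Read a STRING-dialect PPI edge TSV (protein1, protein2, combined_score)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("protein1", "protein2", "combined_score"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    return df


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: term_id <TAB> description <TAB> gene1 <TAB> ...

    The description field may carry a ``category|name`` prefix written by
    :func:`write_gmt`; otherwise the category defaults to "pathway".
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs term, description and >=1 gene")
            term_id, desc = fields[0], fields[1]
            if term_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate term id {term_id}")
            seen.add(term_id)
            category, _, name = desc.partition("|")
            if not name:
                category, name = "pathway", desc
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ValueError(f"{path}:{lineno}: term {term_id} has no genes")
            sets.append(GeneSet(term_id=term_id, term_name=name, members=genes, category=category))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    """Write gene sets as GMT, sorted by term id, members sorted."""
    with open(path, "w", newline="") as fh:
        for gs in sorted(sets, key=lambda s: s.term_id):
            desc = f"{gs.category}|{gs.term_name}"
            fh.write("\t".join([gs.term_id, desc, *sorted(gs.members)]) + "\n")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV output (no index, '\\n' line endings, full precision)."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", quoting=csv.QUOTE_MINIMAL)


def validate_inputs(paths: dict[str, str | Path]) -> dict[str, list[str]]:
    """Schema-check every input file without mutating anything.

    ``paths`` maps input kind (compounds, predictions, disease, ppi, gmt) to
    a file path. Returns kind → list of error strings; an unreadable file
    yields one error and the remaining files are still checked.
    """
    readers = {
        "compounds": read_compound_table,
        "predictions": read_predictions,
        "disease": read_disease_genes,
        "ppi": read_ppi_edges,
        "gmt": read_gmt,
    }
    report: dict[str, list[str]] = {}
    for kind, path in paths.items():
        if kind not in readers:
            report[kind] = [f"unknown input kind {kind!r}"]
            continue
        try:
            readers[kind](path)
            report[kind] = []
        except (OSError, ValueError) as exc:
            report[kind] = [str(exc)]
    return report
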