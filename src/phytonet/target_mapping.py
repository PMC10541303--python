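"""Intersection of compound-predicted targets with disease-associated genes.

Predicted targets (from structure-based target prediction) and disease genes
(with association relevance scores) are intersected by canonical gene symbol;
common genes then pass a relevance-score cutoff to become potential targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = ["VennResult", "canonical_symbol", "intersect_targets", "filter_by_relevance"]


def canonical_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: stripped and upper-cased (idempotent)."""
    return str(symbol).strip().upper()


@dataclass(frozen=True)
class VennResult:
    """Two-set Venn partition of predicted targets vs disease genes."""

    only_predicted: frozenset[str]
    only_disease: frozenset[str]
    common: frozenset[str]
    relevance: Mapping[str, float] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "only_predicted": len(self.only_predicted),
            "only_disease": len(self.only_disease),
            "common": len(self.common),
        }


def intersect_targets(
    predicted: Iterable[str],
    disease: pd.DataFrame | Mapping[str, float],
) -> VennResult:
    """Intersect predicted target symbols with a disease gene table.

    ``disease`` is either a DataFrame with ``symbol`` and ``relevance_score``
    columns or a symbol → score mapping. Relevance scores are carried from the
    disease side for the common genes. Duplicate disease symbols with
    conflicting scores raise.
    """
    pred = {canonical_symbol(s) for s in predicted}
    if isinstance(disease, pd.DataFrame):
        items = [
            (canonical_symbol(row["symbol"]), float(row["relevance_score"]))
            for row in disease.to_dict("records")
        ]
    else:
        items = [(canonical_symbol(s), float(v)) for s, v in disease.items()]
    scores: dict[str, float] = {}
    for sym, score in items:
        if sym in scores and scores[sym] != score:
            raise ValueError(f"conflicting relevance scores for gene {sym}: {scores[sym]} vs {score}")
        scores[sym] = score
    dis = set(scores)
    common = pred & dis
    return VennResult(
        only_predicted=frozenset(pred - dis),
        only_disease=frozenset(dis - pred),
        common=frozenset(common),
        relevance={s: scores[s] for s in common},
    )


def filter_by_relevance(venn: VennResult, min_score: float = 9.0) -> pd.DataFrame:
    """Common genes with relevance score ≥ ``min_score`` (inclusive).

    Returns a DataFrame (symbol, relevance_score) sorted by score descending,
    ties by symbol. A common gene without a score is an error.
    """
    missing = sorted(s for s in venn.common if s not in venn.relevance)
    if missing:
        raise ValueError(f"common genes lack relevance scores: {missing}")
    rows = [
        {"symbol": s, "relevance_score": venn.relevance[s]}
        for s in venn.common
        if venn.relevance[s] >= min_score
    ]
    out = pd.DataFrame(rows, columns=["symbol", "relevance_score"])
    return out.sort_values(
        ["relevance_score", "symbol"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
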