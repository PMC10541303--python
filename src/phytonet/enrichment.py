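"""Gene-set over-representation analysis (hypergeometric, one-sided).

For a query gene set of size n drawn from a universe of size N, a term with
K members has upper-tail probability P(X ≥ k) of overlapping the query in k
or more genes under the hypergeometric null. Raw P < 0.05 is the default
significance filter; Benjamini–Hochberg adjustment is available as a
stricter optional mode. The default universe is the union of all genes in
the annotation collection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .target_mapping import canonical_symbol

__all__ = ["GeneSet", "hypergeom_p", "bh_adjust", "enrich"]


@dataclass(frozen=True)
class GeneSet:
    """An annotation term (pathway or GO category) with its member genes."""

    term_id: str
    term_name: str
    members: frozenset[str]
    category: str = "pathway"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.term_id} has no members")


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X ≥ k).

    X counts the overlap between a size-``n`` draw (the query) and a
    size-``K`` marked subset (the term) in a universe of ``N`` genes.
    Evaluated through the survival function in log-stable form.
    """
    if N < 0 or not (0 <= K <= N) or not (0 <= n <= N):
        raise ValueError(f"impossible hypergeometric configuration K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values with monotonicity enforcement.

    Input order is preserved; results are invariant to permutation of ties.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: Iterable[str],
    collection: Sequence[GeneSet],
    universe: Iterable[str] | None = None,
    p_max: float = 0.05,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Over-representation of ``query`` in every term of ``collection``.

    Terms are intersected with the universe before testing; query genes
    outside the universe are dropped (their count appears in the
    ``n_query_outside_universe`` DataFrame attribute). Terms with zero
    overlap are never reported. With ``adjust="BH"`` the significance filter
    applies to q-values instead of raw p-values.

    Returns a DataFrame (term_id, term_name, category, k, K, n, N, p_value,
    q_value, genes) sorted by ascending p then term_id.
    """
    q = {canonical_symbol(s) for s in query}
    if universe is None:
        uni: set[str] = set()
        for gs in collection:
            uni.update(canonical_symbol(s) for s in gs.members)
    else:
        uni = {canonical_symbol(s) for s in universe}
    if not uni:
        raise ValueError("enrichment universe is empty")
    dropped = len(q - uni)
    q &= uni
    rows = []
    for gs in collection:
        members = {canonical_symbol(s) for s in gs.members} & uni
        k = len(q & members)
        if k == 0 or not members:
            continue
        rows.append(
            {
                "term_id": gs.term_id,
                "term_name": gs.term_name,
                "category": gs.category,
                "k": k,
                "K": len(members),
                "n": len(q),
                "N": len(uni),
                "p_value": hypergeom_p(k, len(members), len(q), len(uni)),
                "genes": ";".join(sorted(q & members)),
            }
        )
    columns = ["term_id", "term_name", "category", "k", "K", "n", "N", "p_value", "q_value", "genes"]
    if not rows:
        out = pd.DataFrame(columns=columns)
        out.attrs["n_query_outside_universe"] = dropped
        return out
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    crit = out["q_value"] if adjust == "BH" else out["p_value"]
    out = out.loc[crit <= p_max]
    out = out.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    out = out[columns]
    out.attrs["n_query_outside_universe"] = dropped
    return out
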