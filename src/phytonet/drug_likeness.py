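"""Quantitative estimate of drug-likeness (QED) and compound screening.

QED maps eight physicochemical descriptors — molecular weight (MW), ALOGP,
hydrogen-bond acceptors (HBA) and donors (HBD), polar surface area (PSA),
rotatable bonds (ROTB), aromatic rings (AROM), and structural-alert count
(ALERTS) — through asymmetric double-sigmoidal (ADS) desirability functions
fit to the property distributions of approved oral drugs, then combines the
eight desirabilities as a (weighted) geometric mean. The ADS coefficients are
the published values of the QED method and ship as a static table.

The screen retains compounds with QED at or above a cutoff (default 0.4) and,
optionally, a TRUE oral-bioavailability (OB) flag, then collapses duplicate
compounds appearing under several herbs into one record with merged origins.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ADSParams",
    "ADS_PARAMS",
    "DESCRIPTOR_NAMES",
    "QED_WEIGHTS",
    "ads_desirability",
    "qed_score",
    "score_compounds",
    "screen_compounds",
    "deduplicate",
    "lipinski_veber_pass",
]

DESCRIPTOR_NAMES = ("MW", "ALOGP", "HBA", "HBD", "PSA", "ROTB", "AROM", "ALERTS")

#: Lower-case column names used in compound tables, aligned with DESCRIPTOR_NAMES.
DESCRIPTOR_COLUMNS = ("mw", "alogp", "hba", "hbd", "psa", "rotb", "arom", "alerts")


class ADSParams(NamedTuple):
    """Coefficients of one asymmetric double sigmoidal desirability function."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float
    dmax: float


# Published ADS coefficients of the QED method, one set per descriptor.
ADS_PARAMS: dict[str, ADSParams] = {
    "MW": ADSParams(2.817065973, 392.5754953, 290.7489764, 2.419764353, 49.22325677, 65.37051707, 104.9805561),
    "ALOGP": ADSParams(3.172690585, 137.8624751, 2.534937431, 4.581497897, 0.822739154, 0.576295591, 131.3186604),
    "HBA": ADSParams(2.948620388, 160.4605972, 3.615294657, 4.435986202, 0.290141953, 1.300669958, 148.7763046),
    "HBD": ADSParams(1.618662227, 1010.051101, 0.985094388, 0.000000000001, 0.713820843, 0.920922555, 258.1632616),
    "PSA": ADSParams(1.876861559, 125.2232657, 62.90773554, 87.83366614, 12.01999824, 28.51324732, 104.5686167),
    "ROTB": ADSParams(0.010000091, 272.4121427, 2.558379970, 1.565547684, 1.271567166, 2.758063707, 105.4420403),
    "AROM": ADSParams(3.217788970, 957.7374108, 2.274627939, 0.000000001, 1.317690384, 0.375760881, 312.3372610),
    "ALERTS": ADSParams(0.010000000, 1199.094025, -0.09002883, 0.000000001, 0.185904477, 0.875193782, 417.7253140),
}

#: Weighting schemes for the geometric mean. "unit" is the unweighted variant;
#: "max_info" are the published maximum-information-content weights.
QED_WEIGHTS: dict[str, tuple[float, ...]] = {
    "unit": (1.0,) * 8,
    "max_info": (0.66, 0.46, 0.05, 0.61, 0.06, 0.65, 0.48, 0.95),
}

# Desirabilities are floored at a tiny positive value so the log-space
# geometric mean is total; the ADS asymptote a/dmax is itself > 1e-5.
_D_FLOOR = 1e-12


def ads_desirability(x: float, params: ADSParams) -> float:
    """ADS desirability of a descriptor value, normalized into (0, 1].

    d(x) = ADS(x) / dmax with
    ADS(x) = a + b · [1 + exp(−(x − c + d/2)/e)]⁻¹ · (1 − [1 + exp(−(x − c − d/2)/f)]⁻¹).
    """
    p = params

    def sigmoid(t: float) -> float:
        # overflow-safe logistic; exact for |t| < 700 (the rdkit-comparable range)
        if t >= 0:
            return 1.0 / (1.0 + math.exp(-t)) if t < 700 else 1.0
        return math.exp(t) / (1.0 + math.exp(t)) if t > -700 else 0.0

    s_rise = sigmoid((x - p.c + p.d / 2.0) / p.e)
    s_fall = sigmoid((x - p.c - p.d / 2.0) / p.f)
    value = (p.a + p.b * s_rise * (1.0 - s_fall)) / p.dmax
    return max(min(value, 1.0), _D_FLOOR)


def qed_score(
    descriptors: Mapping[str, float] | Sequence[float],
    weights: str | Sequence[float] = "unit",
) -> float:
    """QED of one descriptor vector: weighted geometric mean of ADS values.

    QED = exp( Σ wᵢ ln dᵢ / Σ wᵢ ). ``descriptors`` is either a mapping with
    the keys in :data:`DESCRIPTOR_NAMES` or a sequence in that order;
    ``weights`` is a scheme name from :data:`QED_WEIGHTS` or eight
    non-negative reals with a positive sum.
    """
    if isinstance(weights, str):
        w = QED_WEIGHTS[weights]
    else:
        w = tuple(float(v) for v in weights)
    if len(w) != 8 or any(v < 0 for v in w) or sum(w) <= 0:
        raise ValueError("weights must be 8 non-negative values with a positive sum")
    if isinstance(descriptors, Mapping):
        values = [float(descriptors[name]) for name in DESCRIPTOR_NAMES]
    else:
        values = [float(v) for v in descriptors]
        if len(values) != 8:
            raise ValueError(f"expected 8 descriptor values, got {len(values)}")
    log_sum = 0.0
    for name, x, wi in zip(DESCRIPTOR_NAMES, values, w):
        if wi == 0.0:
            continue
        log_sum += wi * math.log(ads_desirability(x, ADS_PARAMS[name]))
    return math.exp(log_sum / sum(w))


def lipinski_veber_pass(row: Mapping[str, float]) -> bool:
    """Rule-of-five plus Veber oral-absorbability gate on descriptor columns."""
    return (
        row["mw"] <= 500
        and row["alogp"] <= 5
        and row["hbd"] <= 5
        and row["hba"] <= 10
        and row["rotb"] <= 10
        and row["psa"] <= 140
    )


def score_compounds(compounds: pd.DataFrame, weights: str | Sequence[float] = "unit") -> pd.DataFrame:
    """Return a copy of the compound table with a ``qed`` column appended.

    Expects the descriptor columns in :data:`DESCRIPTOR_COLUMNS`.
    """
    missing = [c for c in DESCRIPTOR_COLUMNS if c not in compounds.columns]
    if missing:
        raise ValueError(f"compound table is missing descriptor columns: {missing}")
    out = compounds.copy()
    out["qed"] = [
        qed_score([row[c] for c in DESCRIPTOR_COLUMNS], weights=weights)
        for row in compounds[list(DESCRIPTOR_COLUMNS)].to_dict("records")
    ]
    return out


def screen_compounds(
    compounds: pd.DataFrame,
    qed_cutoff: float = 0.4,
    require_ob: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the drug-likeness screen and deduplicate survivors.

    Retains rows with ``qed >= qed_cutoff`` (inclusive boundary) and, when
    ``require_ob``, a true ``ob`` flag; duplicates are then collapsed by
    compound id with herb origins merged. Returns the screened table and a
    funnel dict with ``input`` / ``passed`` / ``deduplicated`` counts.
    """
    if "qed" not in compounds.columns or compounds["qed"].isna().any():
        raise ValueError("compounds must be scored (qed column present, no missing values) before screening")
    mask = compounds["qed"] >= qed_cutoff
    if require_ob:
        mask &= compounds["ob"].astype(bool)
    passed = compounds.loc[mask]
    deduped = deduplicate(passed)
    funnel = {
        "input": int(len(compounds)),
        "passed": int(len(passed)),
        "deduplicated": int(len(deduped)),
    }
    return deduped, funnel


def _merge_herbs(values: Iterable[str]) -> str:
    herbs: set[str] = set()
    for v in values:
        herbs.update(h for h in str(v).split(";") if h)
    return ";".join(sorted(herbs))


def deduplicate(compounds: pd.DataFrame) -> pd.DataFrame:
    """Collapse rows sharing a ``compound_id`` into one record.

    Herb origins (semicolon-separated ``herbs`` column) become the sorted
    union; descriptor values must agree across duplicates, otherwise the
    conflicting ids are reported in the error. Output is sorted by id.
    """
    if compounds.empty:
        return compounds.reset_index(drop=True)
    conflict_cols = [c for c in DESCRIPTOR_COLUMNS if c in compounds.columns]
    conflicts = [
        cid
        for cid, grp in compounds.groupby("compound_id")
        if len(grp) > 1 and any(grp[c].nunique() > 1 for c in conflict_cols)
    ]
    if conflicts:
        raise ValueError(f"conflicting descriptor values for duplicated compound ids: {sorted(conflicts)}")
    agg: dict[str, object] = {c: "first" for c in compounds.columns if c != "compound_id"}
    if "herbs" in compounds.columns:
        agg["herbs"] = _merge_herbs
    out = compounds.groupby("compound_id", as_index=False).agg(agg)
    return out.sort_values("compound_id", kind="mergesort").reset_index(drop=True)
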