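"""Molecular-formula arithmetic for ESI-MS compound identity checks.

Parses Hill-style molecular formulas, computes monoisotopic masses from a
bundled table of most-abundant-isotope exact masses, derives theoretical m/z
for protonated adducts with optional neutral losses (e.g. in-source water
loss), and expresses measured-vs-theoretical deviation in parts per million.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "MolecularFormula",
    "WATER",
    "AdductSpec",
    "MassMatch",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "parse_adduct",
]

# Exact masses (Da) of each element's most abundant isotope, CODATA/IUPAC.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "B": 11.0093054,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "F": 18.99840322,
    "Na": 22.9897692809,
    "Mg": 23.9850417,
    "Si": 27.9769265325,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "K": 38.96370668,
    "Ca": 39.96259098,
    "Fe": 55.9349375,
    "Zn": 63.9291422,
    "Se": 73.9224764,
    "Br": 78.9183371,
    "I": 126.904473,
}

#: Mass of a proton (Da); differs from atomic H by the electron mass, which is
#: the correct increment for an (M+H)+ ion.
PROTON_MASS = 1.00727646

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
# Markup sometimes survives text extraction of formula strings ("C_10_H_10_O_4_").
_MARKUP = re.compile(r"[_^*\s]")


class FormulaError(ValueError):
    """Raised for malformed formula or adduct strings."""


@dataclass(frozen=True)
class MolecularFormula:
    """An elemental composition, e.g. ``{"C": 10, "H": 10, "O": 4}``.

    Counts are strictly positive; only elements in :data:`MONOISOTOPIC_MASS`
    are accepted.
    """

    element_counts: dict[str, int]

    def __post_init__(self) -> None:
        if not self.element_counts:
            raise FormulaError("formula must contain at least one element")
        for elem, count in self.element_counts.items():
            if elem not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element {elem!r}")
            if not isinstance(count, int) or count < 1:
                raise FormulaError(f"count for {elem} must be a positive integer, got {count!r}")

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.element_counts)
        for elem, count in other.element_counts.items():
            merged[elem] = merged.get(elem, 0) + count
        return MolecularFormula(merged)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        def key(e: str) -> tuple[int, str]:
            return ({"C": 0, "H": 1}.get(e, 2), e)

        return "".join(
            f"{e}{c if c > 1 else ''}" for e, c in sorted(self.element_counts.items(), key=lambda kv: key(kv[0]))
        )


WATER = MolecularFormula({"H": 2, "O": 1})


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-style formula string into a :class:`MolecularFormula`.

    Underscore/caret markup is stripped first so table-extracted strings like
    ``"C_10_H_10_O_4_"`` parse verbatim. Repeated element tokens are summed.

    Raises
    ------
    FormulaError
        On an unknown element symbol or a malformed token, naming the
        offending position in the cleaned string.
    """
    cleaned = _MARKUP.sub("", text)
    if not cleaned:
        raise FormulaError(f"empty formula string: {text!r}")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(cleaned):
        m = _TOKEN.match(cleaned, pos)
        if m is None or m.group(1) == "":
            raise FormulaError(f"malformed formula token at position {pos} in {cleaned!r}")
        elem, digits = m.group(1), m.group(2)
        if elem not in MONOISOTOPIC_MASS:
            # A two-letter match may shadow a valid one-letter element ("CO" vs Co).
            if elem[0] in MONOISOTOPIC_MASS and len(elem) == 2:
                elem, digits = elem[0], ""
                pos += 1
            else:
                raise FormulaError(f"unknown element {elem!r} at position {pos} in {cleaned!r}")
        else:
            pos = m.end()
        count = int(digits) if digits else 1
        if count < 1:
            raise FormulaError(f"zero count for element {elem!r} in {cleaned!r}")
        counts[elem] = counts.get(elem, 0) + count
    return MolecularFormula(counts)


def monoisotopic_mass(formula: MolecularFormula | str) -> float:
    """Monoisotopic (most-abundant-isotope) mass of a formula, in Da."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return sum(MONOISOTOPIC_MASS[e] * c for e, c in formula.element_counts.items())


@dataclass(frozen=True)
class AdductSpec:
    """A positive-mode ESI adduct: n protons added, optional neutral losses.

    ``(M+H)+`` is ``AdductSpec(protons_added=1)``; in-source water loss
    ``(M+H)+[-H2O]`` adds one :data:`WATER` neutral loss.
    """

    protons_added: int = 1
    neutral_losses: tuple[MolecularFormula, ...] = ()
    charge: int = 1

    def __post_init__(self) -> None:
        if self.protons_added < 0:
            raise ValueError("protons_added must be >= 0")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")

    @property
    def label(self) -> str:
        core = "M" if self.protons_added == 0 else (
            "M+H" if self.protons_added == 1 else f"M+{self.protons_added}H"
        )
        sign = "+" if self.charge == 1 else f"{self.charge}+"
        losses = "".join(f"[-{loss}]" for loss in self.neutral_losses)
        return f"({core}){sign}{losses}"


_ADDUCT = re.compile(r"^\(M(?:\+(\d*)H)?\)(?:(\d*)\+)((?:\[-[A-Za-z0-9]+\])*)$")


def parse_adduct(text: str) -> AdductSpec:
    """Parse adduct labels like ``(M+H)+``, ``(M+2H)2+`` or ``(M+H)+[-H2O]``.

    Tolerates caret/underscore markup and internal whitespace.
    """
    cleaned = _MARKUP.sub("", text)
    m = _ADDUCT.match(cleaned)
    if m is None:
        raise FormulaError(f"unrecognized adduct label: {text!r}")
    protons = int(m.group(1)) if m.group(1) else (1 if "+H" in cleaned.split(")")[0] else 0)
    charge = int(m.group(2)) if m.group(2) else 1
    losses = tuple(parse_formula(s) for s in re.findall(r"\[-([A-Za-z0-9]+)\]", m.group(3)))
    return AdductSpec(protons_added=protons, neutral_losses=losses, charge=charge)


def adduct_mz(neutral_mass: float, adduct: AdductSpec) -> float:
    """Theoretical m/z of ``adduct`` for a neutral monoisotopic mass (Da).

    m/z = (M − Σ neutral-loss masses + n_H × m_proton) / z.
    """
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    loss = sum(monoisotopic_mass(f) for f in adduct.neutral_losses)
    numerator = neutral_mass - loss + adduct.protons_added * PROTON_MASS
    if numerator <= 0:
        raise ValueError(
            f"neutral losses ({loss:.4f} Da) exceed the precursor mass ({neutral_mass:.4f} Da)"
        )
    return numerator / adduct.charge


def ppm_error(theoretical: float, measured: float) -> float:
    """Signed mass error in ppm: (measured − theoretical) / theoretical × 1e6."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return (measured - theoretical) / theoretical * 1e6


@dataclass(frozen=True)
class MassMatch:
    """A theoretical/measured m/z pair with its ppm deviation."""

    theoretical_mz: float
    measured_mz: float
    error_ppm: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "error_ppm", ppm_error(self.theoretical_mz, self.measured_mz))
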