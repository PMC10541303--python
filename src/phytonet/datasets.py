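"""Bundled example data: seven HPLC-QTOF-MS-identified key compounds.

A small worked dataset from a ten-herb immune-enhancing decoction study:
seven marker compounds identified in positive-mode ESI, each with its
molecular formula, observed adduct, measured m/z, and the key immune targets
(MAPK/STAT/interleukin/TNF axis) it correlates with in the
compound–target–pathway network. Useful for demonstrating the mass
arithmetic and network-ranking APIs on real published-scale numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["KeyCompound", "KEY_COMPOUNDS", "KEY_TARGETS", "compound_target_edges"]


@dataclass(frozen=True)
class KeyCompound:
    name: str
    formula: str
    adduct: str
    measured_mz: float
    targets: tuple[str, ...]


#: Nine key immune targets selected by PPI topological filtering in the
#: source screen (degree/betweenness/closeness criteria).
KEY_TARGETS = ("IL1B", "IL2", "IL6", "MAPK14", "MAPK3", "SRC", "STAT1", "STAT3", "TNF")

KEY_COMPOUNDS = (
    KeyCompound("Ferulic acid", "C10H10O4", "(M+H)+[-H2O]", 177.0541, ("TNF", "IL6", "STAT3")),
    KeyCompound("Isoglabrolide", "C30H44O4", "(M+H)+", 469.3317, ("IL1B", "MAPK14", "STAT3")),
    KeyCompound("Neocnidilide", "C12H18O2", "(M+H)+", 195.1372, ("IL1B", "MAPK14", "STAT3")),
    KeyCompound("Glabric acid", "C30H46O5", "(M+H)+", 487.3424, ("TNF", "IL6", "MAPK3")),
    KeyCompound("Liquiritic acid", "C30H46O4", "(M+H)+[-H2O]", 453.3367, ("TNF", "IL6", "MAPK3")),
    KeyCompound("Scopoletin", "C10H8O4", "(M+H)+[-H2O]", 175.0381, ("TNF", "IL1B", "MAPK14", "STAT3")),
    KeyCompound("Erybacin B", "C19H18O5", "(M+H)+", 327.1236, ("TNF", "STAT3", "MAPK14")),
)


def compound_target_edges() -> list[tuple[str, str]]:
    """Compound→target edge list of the bundled key-compound dataset."""
    return [(c.name, t) for c in KEY_COMPOUNDS for t in c.targets]
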