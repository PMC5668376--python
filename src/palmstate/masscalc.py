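"""Protein and modification mass arithmetic for palmitoyl-ladder prediction.

Native MS of intact membrane proteins resolves *average* masses, so average
is the default mass kind everywhere; monoisotopic masses are supported for
completeness. Atomic weights are IUPAC 2013 standard values, baked in to six
decimals. Cysteines are treated as free thiols; modifications enter only as
explicit delta masses such as :func:`palmitoyl_delta`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping

from Bio import SeqIO

__all__ = [
    "ElementComposition",
    "MassValue",
    "protein_mass",
    "palmitoyl_delta",
    "read_fasta",
    "WATER",
    "PALMITOYL",
    "PROTON_MASS",
]

# IUPAC 2013 standard atomic weights (abridged), Da.
AVERAGE_WEIGHTS: Mapping[str, float] = {
    "H": 1.008000,
    "C": 12.011000,
    "N": 14.007000,
    "O": 15.999000,
    "S": 32.060000,
}

# Principal-isotope masses, Da.
MONOISOTOPIC_WEIGHTS: Mapping[str, float] = {
    "H": 1.007825,
    "C": 12.000000,
    "N": 14.003074,
    "O": 15.994915,
    "S": 31.972071,
}

#: Mass of a proton used for charge-state arithmetic (Da).
PROTON_MASS = 1.00728


@dataclass(frozen=True)
class ElementComposition:
    """Chemical composition as non-negative element counts."""

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for element, count in self.counts.items():
            if element not in AVERAGE_WEIGHTS:
                raise ValueError(f"unsupported element {element!r}")
            if count < 0:
                raise ValueError(f"negative count for element {element!r}")

    def __add__(self, other: "ElementComposition") -> "ElementComposition":
        merged = dict(self.counts)
        for element, count in other.counts.items():
            merged[element] = merged.get(element, 0) + count
        return ElementComposition(merged)

    def mass(self, kind: str = "average") -> "MassValue":
        weights = _weights(kind)
        value = sum(count * weights[el] for el, count in self.counts.items())
        return MassValue(value, kind)


@dataclass(frozen=True)
class MassValue:
    """A mass in daltons tagged with its kind (average or monoisotopic).

    The kind is fixed at construction and propagates through arithmetic;
    mixing kinds raises, which catches average/monoisotopic bookkeeping
    errors early.
    """

    value: float
    kind: str = "average"

    def __post_init__(self) -> None:
        if self.kind not in ("average", "monoisotopic"):
            raise ValueError(f"unknown mass kind {self.kind!r}")
        if self.value < 0:
            raise ValueError("mass must be non-negative")

    def _check(self, other: "MassValue") -> None:
        if self.kind != other.kind:
            raise ValueError(f"cannot mix {self.kind} and {other.kind} masses")

    def __add__(self, other: "MassValue") -> "MassValue":
        self._check(other)
        return MassValue(self.value + other.value, self.kind)

    def __sub__(self, other: "MassValue") -> "MassValue":
        self._check(other)
        return MassValue(self.value - other.value, self.kind)

    def __float__(self) -> float:
        return self.value


def _weights(kind: str) -> Mapping[str, float]:
    if kind == "average":
        return AVERAGE_WEIGHTS
    if kind == "monoisotopic":
        return MONOISOTOPIC_WEIGHTS
    raise ValueError(f"unknown mass kind {kind!r}")


#: One water molecule — the N- and C-terminal H/OH of a peptide chain.
WATER = ElementComposition({"H": 2, "O": 1})

#: Palmitoyl modification: palmitic acid minus water (thioester-linked acyl),
#: C16H30O, the 238 Da ladder increment of S-palmitoylation.
PALMITOYL = ElementComposition({"C": 16, "H": 30, "O": 1})

# Residue (amino acid minus water) compositions of the 20 canonical residues.
RESIDUE_COMPOSITIONS: Dict[str, ElementComposition] = {
    "G": ElementComposition({"C": 2, "H": 3, "N": 1, "O": 1}),
    "A": ElementComposition({"C": 3, "H": 5, "N": 1, "O": 1}),
    "S": ElementComposition({"C": 3, "H": 5, "N": 1, "O": 2}),
    "P": ElementComposition({"C": 5, "H": 7, "N": 1, "O": 1}),
    "V": ElementComposition({"C": 5, "H": 9, "N": 1, "O": 1}),
    "T": ElementComposition({"C": 4, "H": 7, "N": 1, "O": 2}),
    "C": ElementComposition({"C": 3, "H": 5, "N": 1, "O": 1, "S": 1}),
    "L": ElementComposition({"C": 6, "H": 11, "N": 1, "O": 1}),
    "I": ElementComposition({"C": 6, "H": 11, "N": 1, "O": 1}),
    "N": ElementComposition({"C": 4, "H": 6, "N": 2, "O": 2}),
    "D": ElementComposition({"C": 4, "H": 5, "N": 1, "O": 3}),
    "Q": ElementComposition({"C": 5, "H": 8, "N": 2, "O": 2}),
    "K": ElementComposition({"C": 6, "H": 12, "N": 2, "O": 1}),
    "E": ElementComposition({"C": 5, "H": 7, "N": 1, "O": 3}),
    "M": ElementComposition({"C": 5, "H": 9, "N": 1, "O": 1, "S": 1}),
    "H": ElementComposition({"C": 6, "H": 7, "N": 3, "O": 1}),
    "F": ElementComposition({"C": 9, "H": 9, "N": 1, "O": 1}),
    "R": ElementComposition({"C": 6, "H": 12, "N": 4, "O": 1}),
    "Y": ElementComposition({"C": 9, "H": 9, "N": 1, "O": 2}),
    "W": ElementComposition({"C": 11, "H": 10, "N": 2, "O": 1}),
}


def protein_mass(
    sequence: str,
    kind: str = "average",
    remove_initiator_met: bool = False,
) -> MassValue:
    """Neutral mass of an unmodified protein chain.

    Parameters
    ----------
    sequence
        Amino-acid sequence in one-letter code (canonical 20 only).
    kind
        ``"average"`` (default, what intact-protein native MS resolves) or
        ``"monoisotopic"``.
    remove_initiator_met
        Subtract the Met residue mass when the sequence starts with M,
        modelling co-translational initiator-methionine excision — mature
        membrane proteins are typically observed without it.
    """
    composition = WATER
    for position, letter in enumerate(sequence):
        residue = RESIDUE_COMPOSITIONS.get(letter)
        if residue is None:
            raise ValueError(
                f"non-canonical residue {letter!r} at position {position}"
            )
        composition = composition + residue
    mass = composition.mass(kind)
    if remove_initiator_met and sequence.startswith("M"):
        mass = mass - RESIDUE_COMPOSITIONS["M"].mass(kind)
    return mass


def palmitoyl_delta(kind: str = "average") -> MassValue:
    """Mass added per S-palmitoylation event (C16H30O; ~238.4 Da average)."""
    return PALMITOYL.mass(kind)


def read_fasta(path: str | Path) -> Dict[str, str]:
    """Read single- or multi-record FASTA; sequences keyed by record id."""
    records: Dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in records:
            raise ValueError(f"duplicate FASTA record id {record.id!r}")
        records[record.id] = str(record.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records
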