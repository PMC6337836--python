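"""Monoisotopic mass arithmetic for residues, peptides, and tryptic digestion.

The mapping stages reason entirely in monoisotopic mass space: a peptide
sequence tag carries the masses of its flanking fragment ions, and every
placement on the genome is verified by summing residue masses on either side
of the tag.  This module holds the frozen residue mass table, the fragment-ion
offset constants, the modification definitions, and in-silico trypsin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Tuple

__all__ = [
    "MONOISOTOPIC",
    "WATER",
    "PROTON",
    "Modification",
    "CARBAMIDOMETHYL",
    "OXIDATION",
    "DEFAULT_MODIFICATIONS",
    "MassConstants",
    "sum_residue_masses",
    "peptide_neutral_mass",
    "tryptic_digest",
]

#: Monoisotopic residue (amino-acid minus water) masses in daltons.
#: Leucine and isoleucine are exact isobars, which is why tag matching treats
#: them as equivalent downstream.
MONOISOTOPIC = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047679,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

#: Monoisotopic mass of H2O (Da), the difference between a peptide's neutral
#: mass and the sum of its residue masses.
WATER = 18.0105646

#: Mass of a proton (Da); singly protonated fragment ions carry one.
PROTON = 1.00727646


@dataclass(frozen=True)
class Modification:
    """A post-translational modification as a mass shift on one residue type."""

    name: str
    target: str
    delta: float

    def __post_init__(self) -> None:
        if self.target not in MONOISOTOPIC:
            raise ValueError(f"modification target {self.target!r} is not a canonical residue")
        if not (self.delta == self.delta and abs(self.delta) < float("inf")):
            raise ValueError("modification delta must be finite")


#: Fixed cysteine carbamidomethylation, nominally "+57".
CARBAMIDOMETHYL = Modification("carbamidomethyl", "C", 57.021464)

#: Variable methionine oxidation, nominally "+16".
OXIDATION = Modification("oxidation", "M", 15.994915)

DEFAULT_MODIFICATIONS: Tuple[Modification, ...] = (CARBAMIDOMETHYL, OXIDATION)


@dataclass(frozen=True)
class MassConstants:
    """Offsets relating residue-mass sums to observed flank-ion masses.

    The N-flank mass of a tag is modelled as a singly charged b ion of the
    residues preceding the tag (residue sum + proton); the C-flank as a singly
    charged y ion of the residues following it (residue sum + water + proton).
    Both offsets are configurable because de novo engines differ in whether
    they report proton- or hydrogen-referenced ion masses.
    """

    proton: float = PROTON
    water: float = WATER
    n_flank_offset: float = PROTON
    c_flank_offset: float = WATER + PROTON


def _check_residues(seq: str) -> None:
    for ch in seq:
        if ch not in MONOISOTOPIC:
            raise ValueError(f"unknown residue {ch!r} in sequence {seq!r}")


def sum_residue_masses(
    seq: str, applied_mods: Iterable[Tuple[int, Modification]] = ()
) -> float:
    """Sum of monoisotopic residue masses of ``seq`` plus modification deltas.

    ``applied_mods`` is an iterable of ``(position, Modification)`` pairs; each
    modification must target the residue actually present at its position.
    The result is additive and independent of residue order.
    """
    _check_residues(seq)
    total = sum(MONOISOTOPIC[ch] for ch in seq)
    for pos, mod in applied_mods:
        if not 0 <= pos < len(seq):
            raise ValueError(f"modification position {pos} outside sequence of length {len(seq)}")
        if seq[pos] != mod.target:
            raise ValueError(
                f"modification {mod.name} targets {mod.target} but position {pos} is {seq[pos]!r}"
            )
        total += mod.delta
    return total


def peptide_neutral_mass(
    seq: str, applied_mods: Iterable[Tuple[int, Modification]] = ()
) -> float:
    """Neutral (uncharged) monoisotopic peptide mass: residue sum + H2O."""
    return sum_residue_masses(seq, applied_mods) + WATER


def tryptic_digest(
    protein: str, missed_cleavages: int = 0, proline_rule: bool = True
) -> List[Tuple[str, int, int]]:
    """In-silico trypsin: cleave C-terminal to K/R, optionally not before P.

    Returns every peptide with at most ``missed_cleavages`` internal cleavage
    sites as ``(peptide, start, end)`` with 0-based half-open coordinates in
    ``protein``.  The 0-missed-cleavage peptides concatenate back to the
    protein.
    """
    if not protein:
        raise ValueError("protein sequence is empty")
    _check_residues(protein)
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    n = len(protein)
    boundaries = [0]
    for i, ch in enumerate(protein[:-1]):
        if ch in "KR" and not (proline_rule and protein[i + 1] == "P"):
            boundaries.append(i + 1)
    boundaries.append(n)
    peptides: List[Tuple[str, int, int]] = []
    nfrag = len(boundaries) - 1
    for i in range(nfrag):
        for j in range(i, min(i + missed_cleavages + 1, nfrag)):
            start, end = boundaries[i], boundaries[j + 1]
            peptides.append((protein[start:end], start, end))
    return peptides
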