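"""Elemental formulae and exact-mass arithmetic for CHNOS dissolved organic matter.

All masses are monoisotopic and come from a single fixed isotope table
(CODATA/IUPAC values).  Formulae are neutral compositions; ions are
even-electron deprotonated species [M-nH]^n-, the convention for
negative-mode electrospray of natural organic matter.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ISOTOPE_MASS",
    "PROTON_MASS",
    "C13_C12_DELTA",
    "CH2_MASS",
    "MolecularFormula",
    "monoisotopic_mass",
    "dbe",
    "mz_deprotonated",
]

#: Monoisotopic masses of the principal isotopes, Da.
ISOTOPE_MASS = {
    "C": 12.0,  # exact by definition
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

#: Mass of the proton, Da (subtracted per charge for [M-nH]^n- ions).
PROTON_MASS = 1.007276467

#: 13C - 12C mass difference, Da; the spacing of the first carbon
#: isotopologue satellite for a singly charged ion.
C13_C12_DELTA = 1.0033548378

#: Exact mass of a CH2 unit, the spacing of homologous series, Da.
CH2_MASS = ISOTOPE_MASS["C"] + 2 * ISOTOPE_MASS["H"]

#: Natural abundance ratio 13C/12C; satellite intensity is ~ c * this.
C13_ABUNDANCE_RATIO = 0.0107 / 0.9893


@dataclass(frozen=True, order=True)
class MolecularFormula:
    """A neutral C_c H_h N_n O_o S_s composition (phosphorus fixed at zero).

    Identity is the atom-count tuple, so stoichiometric isomers are one
    object — consistent with formula-level (not structure-level) analysis.
    """

    c: int
    h: int
    n: int = 0
    o: int = 0
    s: int = 0

    def __post_init__(self) -> None:
        if self.c < 1:
            raise ValueError("a molecular formula requires c >= 1")
        if min(self.h, self.n, self.o, self.s) < 0:
            raise ValueError("negative atom counts are not allowed")

    @property
    def oc_ratio(self) -> float:
        """O/C, the oxidation axis of the Van Krevelen diagram."""
        return self.o / self.c

    @property
    def hc_ratio(self) -> float:
        """H/C, the saturation axis of the Van Krevelen diagram."""
        return self.h / self.c

    @property
    def dbe(self) -> float:
        return dbe(self)

    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self)

    @property
    def heteroatoms(self) -> int:
        """N + S count, used to rank competing assignments."""
        return self.n + self.s

    @property
    def family(self) -> str:
        """Heteroatom family label: CHO, CHON, CHOS or CHNOS."""
        if self.n and self.s:
            return "CHNOS"
        if self.n:
            return "CHON"
        if self.s:
            return "CHOS"
        return "CHO"

    def __str__(self) -> str:
        parts = [f"C{self.c}", f"H{self.h}"]
        if self.n:
            parts.append(f"N{self.n}")
        if self.o:
            parts.append(f"O{self.o}")
        if self.s:
            parts.append(f"S{self.s}")
        return "".join(parts)

    @classmethod
    def from_string(cls, text: str) -> "MolecularFormula":
        """Parse a plain Hill-style CHNOS string like ``C20H20O10``."""
        import re

        counts = {"C": 0, "H": 0, "N": 0, "O": 0, "S": 0}
        pos = 0
        for m in re.finditer(r"([CHNOS])(\d*)", text):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            counts[m.group(1)] += int(m.group(2) or 1)
            pos = m.end()
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(c=counts["C"], h=counts["H"], n=counts["N"],
                   o=counts["O"], s=counts["S"])


def monoisotopic_mass(formula: MolecularFormula) -> float:
    """Neutral monoisotopic mass in Da."""
    m = ISOTOPE_MASS
    return (formula.c * m["C"] + formula.h * m["H"] + formula.n * m["N"]
            + formula.o * m["O"] + formula.s * m["S"])


def dbe(formula: MolecularFormula) -> float:
    """Double bond equivalents: C + 1 - (H - N - P)/2, with P = 0.

    Rings plus double bonds implied by the composition; a half-integer
    value marks an odd-electron/radical composition, which negative-mode
    even-electron assignment rejects.
    """
    return formula.c + 1 - (formula.h - formula.n) / 2.0


def mz_deprotonated(formula: MolecularFormula, charge: int = 1) -> float:
    """m/z of the [M-nH]^n- ion of a neutral formula.

    The proton mass (not the hydrogen-atom mass) is subtracted per
    charge, i.e. the electrons stay with the anion.
    """
    if charge <= 0:
        raise ValueError("charge must be a positive integer")
    if formula.h < charge:
        raise ValueError(
            f"{formula} has only {formula.h} H; cannot remove {charge} protons")
    return (monoisotopic_mass(formula) - charge * PROTON_MASS) / charge


def neutral_mass_from_mz(mz: float, charge: int = 1) -> float:
    """Invert :func:`mz_deprotonated`: neutral mass from observed m/z."""
    if charge <= 0:
        raise ValueError("charge must be a positive integer")
    return mz * charge + charge * PROTON_MASS
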