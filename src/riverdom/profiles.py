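"""Van Krevelen compound classes, intensity-weighted densities and
number-averaged molecular descriptors.

The seven stoichiometric regions (aliphatics, N-saturated
peptides/amino-sugars, low-oxidized and oxidized lignins, condensed and
hydrolysable tannins, carbohydrates) follow the Kellerman-style O/C-H/C
boundaries used throughout the DOM literature; everything outside the
regions is an explicit eighth "unclassified" label so that the
intensity-weighted densities form an exact partition of unity.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assign import AssignmentResult
from .chem import MolecularFormula

__all__ = [
    "CompoundClass",
    "SampleEnsemble",
    "classify",
    "class_densities",
    "stoichiometry_shares",
    "number_averaged",
    "common_formulae",
    "unique_formulae",
    "vk_table",
]


class CompoundClass(str, enum.Enum):
    ALIPHATICS = "aliphatics"
    N_SATURATED = "n_saturated"
    LIGNIN_LOW_OX = "lignin_low_ox"
    LIGNIN_OX = "lignin_ox"
    TANNIN_CONDENSED = "tannin_condensed"
    TANNIN_HYDROLYSABLE = "tannin_hydrolysable"
    CARBOHYDRATES = "carbohydrates"
    UNCLASSIFIED = "unclassified"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The seven named classes, in their conventional reporting order.
NAMED_CLASSES = [c for c in CompoundClass if c is not CompoundClass.UNCLASSIFIED]


def classify(formula: MolecularFormula) -> CompoundClass:
    """Assign the single compound-class label of a formula.

    Boundary semantics are exactly as conventionally printed
    (left-closed, right-open where written "<= ... <").  The N-saturated
    region is tested first for N-containing formulae because it overlaps
    the aliphatic/lignin regions and is defined by the presence of
    nitrogen; the remaining (mutually overlapping only for
    carbohydrates/oxidized-lignin corners) regions are tested in the
    conventional printed order.
    """
    oc, hc = formula.oc_ratio, formula.hc_ratio
    if formula.n >= 1 and 0.1 <= oc < 0.65 and 1.0 <= hc < 2.2:
        return CompoundClass.N_SATURATED
    if 0.0 < oc < 0.65 and 1.6 <= hc < 2.2:
        return CompoundClass.ALIPHATICS
    if 0.1 <= oc < 0.5 and 0.7 <= hc < 1.6:
        return CompoundClass.LIGNIN_LOW_OX
    if 0.5 <= oc < 1.0 and 0.7 <= hc < 1.6:
        return CompoundClass.LIGNIN_OX
    if 0.0 < oc < 0.5 and 0.3 <= hc < 0.7:
        return CompoundClass.TANNIN_CONDENSED
    if 0.5 <= oc < 1.0 and 0.3 <= hc < 0.7:
        return CompoundClass.TANNIN_HYDROLYSABLE
    if 0.65 <= oc < 1.0 and 1.3 <= hc < 2.2:
        return CompoundClass.CARBOHYDRATES
    return CompoundClass.UNCLASSIFIED


@dataclass
class SampleEnsemble:
    """Assigned formulae of one sample with sum-normalized intensities.

    The relative intensities are the unit of every downstream statistic
    (class densities, correlation mapping); they sum to one.
    """

    sample_id: str
    members: dict[MolecularFormula, float]

    def __post_init__(self) -> None:
        if self.members:
            total = float(sum(self.members.values()))
            if total <= 0:
                raise ValueError("ensemble intensities must be positive")
            if abs(total - 1.0) > 1e-9:
                self.members = {f: i / total for f, i in self.members.items()}
            if any(i <= 0 for i in self.members.values()):
                raise ValueError("relative intensities must be in (0, 1]")

    @classmethod
    def from_assignment(cls, result: AssignmentResult) -> "SampleEnsemble":
        members: dict[MolecularFormula, float] = {}
        for a in result.assignments:
            # duplicate formulae (shoulder peaks) accumulate
            members[a.formula] = members.get(a.formula, 0.0) + a.peak.intensity
        return cls(sample_id=result.sample_id, members=members)

    def formulae(self) -> set[MolecularFormula]:
        return set(self.members)

    def __len__(self) -> int:
        return len(self.members)


def class_densities(ensemble: SampleEnsemble) -> pd.Series:
    """Intensity-weighted population density D_k per compound class.

    D_k is the summed relative intensity of the class members over the
    total relative intensity; across the eight labels the densities sum
    to one exactly (up to float round-off).
    """
    if not ensemble.members:
        raise ValueError("cannot profile an empty ensemble")
    d = {c.value: 0.0 for c in CompoundClass}
    for f, i in ensemble.members.items():
        d[classify(f).value] += i
    total = sum(d.values())
    s = pd.Series(d, name=ensemble.sample_id) / total
    return s


def stoichiometry_shares(ensemble: SampleEnsemble) -> pd.Series:
    """Count-based percentage of CHO / CHON / CHOS / CHNOS assignments."""
    counts = {"pct_cho": 0, "pct_chon": 0, "pct_chos": 0, "pct_chnos": 0}
    for f in ensemble.members:
        counts["pct_" + f.family.lower()] += 1
    n = max(len(ensemble.members), 1)
    return pd.Series({k: 100.0 * v / n for k, v in counts.items()},
                     name=ensemble.sample_id)


def number_averaged(ensemble: SampleEnsemble,
                    intensity_weighted: bool = False) -> pd.Series:
    """Number-averaged descriptors: formula count, family %, M_n, O/C_n,
    H/C_n, DBE_n.

    Number-averaged means unweighted arithmetic means over the distinct
    formulae; ``intensity_weighted=True`` switches to relative-intensity
    weights for sensitivity analysis.
    """
    if not ensemble.members:
        raise ValueError("cannot profile an empty ensemble")
    formulas = list(ensemble.members)
    if intensity_weighted:
        w = np.array([ensemble.members[f] for f in formulas])
        w = w / w.sum()
    else:
        w = np.full(len(formulas), 1.0 / len(formulas))
    mass = np.array([f.monoisotopic_mass for f in formulas])
    oc = np.array([f.oc_ratio for f in formulas])
    hc = np.array([f.hc_ratio for f in formulas])
    de = np.array([f.dbe for f in formulas])
    shares = stoichiometry_shares(ensemble)
    return pd.Series({
        "n_formulae": len(formulas),
        "pct_cho": shares["pct_cho"],
        "pct_chon": shares["pct_chon"],
        "pct_chos": shares["pct_chos"],
        "pct_chnos": shares["pct_chnos"],
        "m_n": float(w @ mass),
        "oc_n": float(w @ oc),
        "hc_n": float(w @ hc),
        "dbe_n": float(w @ de),
    }, name=ensemble.sample_id)


def common_formulae(samples: list[SampleEnsemble]) -> set[MolecularFormula]:
    """Formulae present in every sample of the set."""
    if len(samples) < 2:
        raise ValueError("common formulae need at least two samples")
    common = samples[0].formulae()
    for s in samples[1:]:
        common &= s.formulae()
    return common


def unique_formulae(samples: list[SampleEnsemble],
                    max_occurrence: int = 2
                    ) -> dict[str, set[MolecularFormula]]:
    """Per sample, the formulae seen in at most ``max_occurrence`` samples."""
    if len(samples) < 3:
        raise ValueError("unique formulae need at least three samples")
    counts: dict[MolecularFormula, int] = {}
    for s in samples:
        for f in s.formulae():
            counts[f] = counts.get(f, 0) + 1
    return {s.sample_id: {f for f in s.formulae()
                          if counts[f] <= max_occurrence}
            for s in samples}


def vk_table(ensemble: SampleEnsemble) -> pd.DataFrame:
    """Van Krevelen export: one row per formula with class and family.

    Deterministically ordered by (O/C, H/C, mass); ready for plotting or
    delimited-text export.
    """
    rows = [{
        "formula": str(f),
        "oc": f.oc_ratio,
        "hc": f.hc_ratio,
        "mass": f.monoisotopic_mass,
        "intensity": i,
        "compound_class": classify(f).value,
        "family": f.family,
    } for f, i in ensemble.members.items()]
    df = pd.DataFrame(rows, columns=["formula", "oc", "hc", "mass",
                                     "intensity", "compound_class", "family"])
    if len(df):
        df = df.sort_values(["oc", "hc", "mass"], kind="mergesort")
        df = df.reset_index(drop=True)
    return df
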