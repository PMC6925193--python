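"""Elemental formula assignment for negative-mode DOM peak lists.

Each singly charged, calibrated peak is matched against every neutral
CHNOS composition whose [M-H]- mass lies within the ppm tolerance and
which satisfies the standard DOM constraint box (O/C <= 1, H/C <= 2,
C <= 120, H <= 200, 0 < O <= 60, N <= 2, S <= 1), a non-negative integer
DBE (even-electron ions) and h >= 1.  Competing candidates are resolved
heteroatom-minimal first, then by mass error; unresolved ties are
declared ambiguous and excluded downstream.

The candidate search is vectorized: compositions are enumerated once
over (c, o, n, s), sorted by their H-free partial mass, and a binary
search restricts each query to the slab that can reach the target mass
with 0..max_h hydrogens.  Within the slab the hydrogen count is the
nearest integer of the mass residual (a 1 ppm window at 800 Da is
0.0008 Da, far below one hydrogen), with parity fixed by the
even-electron condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import ISOTOPE_MASS, MolecularFormula, neutral_mass_from_mz
from .peaks import MassPeakList, MassPeak

__all__ = [
    "AtomicConstraints",
    "AssignedPeak",
    "AssignmentResult",
    "enumerate_candidates",
    "resolve_ambiguity",
    "assign_formulae",
]

_MH = ISOTOPE_MASS["H"]


@dataclass(frozen=True)
class AtomicConstraints:
    """The DOM assignment constraint box."""

    max_c: int = 120
    max_h: int = 200
    max_n: int = 2
    max_s: int = 1
    o_min: int = 1      # "0 < O" — every DOM formula carries oxygen
    o_max: int = 60
    oc_max: float = 1.0
    hc_max: float = 2.0

    def admits(self, f: MolecularFormula) -> bool:
        return (1 <= f.c <= self.max_c
                and 0 <= f.h <= self.max_h
                and f.n <= self.max_n
                and f.s <= self.max_s
                and self.o_min <= f.o <= self.o_max
                and f.oc_ratio <= self.oc_max
                and f.hc_ratio <= self.hc_max)


@dataclass(frozen=True)
class AssignedPeak:
    peak: MassPeak
    formula: MolecularFormula
    error_ppm: float
    candidates_considered: int


@dataclass
class AssignmentResult:
    sample_id: str
    assignments: list[AssignedPeak]
    n_unassigned: int
    n_ambiguous: int
    n_excluded_charge: int

    def __iter__(self):
        return iter(self.assignments)

    def __len__(self):
        return len(self.assignments)


class _CandidateGrid:
    """(c, o, n, s) partial-mass table shared across queries."""

    def __init__(self, constraints: AtomicConstraints):
        c = np.arange(1, constraints.max_c + 1)
        o = np.arange(constraints.o_min, constraints.o_max + 1)
        n = np.arange(0, constraints.max_n + 1)
        s = np.arange(0, constraints.max_s + 1)
        C, O, N, S = np.meshgrid(c, o, n, s, indexing="ij")
        C, O, N, S = (x.ravel() for x in (C, O, N, S))
        keep = O <= C * constraints.oc_max  # O/C bound is H-free
        self.c, self.o, self.n, self.s = C[keep], O[keep], N[keep], S[keep]
        self.base = (self.c * ISOTOPE_MASS["C"] + self.o * ISOTOPE_MASS["O"]
                     + self.n * ISOTOPE_MASS["N"] + self.s * ISOTOPE_MASS["S"])
        order = np.argsort(self.base)
        for name in ("c", "o", "n", "s", "base"):
            setattr(self, name, getattr(self, name)[order])
        self.constraints = constraints


_GRID_CACHE: dict[AtomicConstraints, _CandidateGrid] = {}


def _grid(constraints: AtomicConstraints) -> _CandidateGrid:
    if constraints not in _GRID_CACHE:
        _GRID_CACHE[constraints] = _CandidateGrid(constraints)
    return _GRID_CACHE[constraints]


def enumerate_candidates(mz: float,
                         constraints: AtomicConstraints,
                         tol_ppm: float = 0.5,
                         charge: int = 1) -> list[tuple[MolecularFormula, float]]:
    """All in-box neutral formulae whose [M-zH]z- m/z is within tol_ppm.

    Returns (formula, signed ppm error) pairs, error measured as
    (observed - theoretical)/theoretical * 1e6.
    """
    g = _grid(constraints)
    target = neutral_mass_from_mz(mz, charge)
    tol_da = target * tol_ppm * 1e-6

    lo = np.searchsorted(g.base, target - g.constraints.max_h * _MH - tol_da)
    hi = np.searchsorted(g.base, target - _MH * charge + tol_da, side="right")
    if lo >= hi:
        return []

    base = g.base[lo:hi]
    c, o, n, s = g.c[lo:hi], g.o[lo:hi], g.n[lo:hi], g.s[lo:hi]
    h = np.rint((target - base) / _MH).astype(int)
    # even-electron neutral: DBE integral requires (h - n) even
    parity_ok = (h - n) % 2 == 0
    mass = base + h * _MH
    err_da = target - mass
    dbe2 = 2 * (c + 1) - (h - n)  # 2*DBE, must be >= 0
    ok = (parity_ok
          & (np.abs(err_da) <= tol_da)
          & (h >= charge)
          & (h <= g.constraints.max_h)
          & (h <= g.constraints.hc_max * c)
          & (dbe2 >= 0))
    out = []
    for i in np.nonzero(ok)[0]:
        f = MolecularFormula(int(c[i]), int(h[i]), int(n[i]), int(o[i]), int(s[i]))
        err_ppm = (target - (base[i] + h[i] * _MH)) / (base[i] + h[i] * _MH) * 1e6
        out.append((f, float(err_ppm)))
    out.sort(key=lambda t: (abs(t[1]), t[0]))
    return out


def resolve_ambiguity(candidates: list[tuple[MolecularFormula, float]]
                      ) -> MolecularFormula | None:
    """Pick one formula from competing candidates, or declare ambiguity.

    Rules, in order: fewest heteroatoms (N+S); smallest absolute mass
    error; a residual tie returns None and the peak is excluded from
    downstream statistics.
    """
    if not candidates:
        raise ValueError("resolve_ambiguity requires at least one candidate")
    if len(candidates) == 1:
        return candidates[0][0]
    ranked = sorted(candidates, key=lambda t: (t[0].heteroatoms, abs(t[1])))
    (f0, e0), (f1, e1) = ranked[0], ranked[1]
    if f0.heteroatoms == f1.heteroatoms and abs(e0) == abs(e1):
        return None
    return f0


def assign_formulae(peak_list: MassPeakList,
                    constraints: AtomicConstraints | None = None,
                    tol_ppm: float = 0.5,
                    require_calibrated: bool = True) -> AssignmentResult:
    """Assign every eligible peak of a calibrated list to one formula.

    Peaks flagged as isotopologues or with charge != 1 are excluded;
    peaks with no in-tolerance candidate or an unresolvable tie are
    counted but omitted.
    """
    if require_calibrated and peak_list.calibration_state != "calibrated":
        raise ValueError(
            "peak list is not calibrated; recalibrate first or pass "
            "require_calibrated=False")
    constraints = constraints or AtomicConstraints()
    assignments: list[AssignedPeak] = []
    n_unassigned = n_ambiguous = n_excluded = 0
    for p in peak_list.peaks:
        if p.is_isotopologue or p.charge != 1:
            n_excluded += 1
            continue
        cands = enumerate_candidates(p.mz, constraints, tol_ppm, charge=1)
        if not cands:
            n_unassigned += 1
            continue
        f = resolve_ambiguity(cands)
        if f is None:
            n_ambiguous += 1
            continue
        err = next(e for fc, e in cands if fc == f)
        assignments.append(AssignedPeak(peak=p, formula=f, error_ppm=err,
                                        candidates_considered=len(cands)))
    return AssignmentResult(sample_id=peak_list.sample_id,
                            assignments=assignments,
                            n_unassigned=n_unassigned,
                            n_ambiguous=n_ambiguous,
                            n_excluded_charge=n_excluded)
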