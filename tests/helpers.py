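"""Independent brute-force oracles used to check the optimized paths."""

from riverdom.assign import AtomicConstraints
from riverdom.chem import ISOTOPE_MASS, MolecularFormula, PROTON_MASS


def brute_force_candidates(mz: float, constraints: AtomicConstraints,
                           tol_ppm: float, charge: int = 1):
    """Exhaustive CHNOS enumeration over the full constraint box.

    Plain nested loops over (c, o, n, s); for each partial composition
    the four integers bracketing the hydrogen count implied by the mass
    residual are each checked with independent mass arithmetic (any
    other h is at least ~1 Da off, far beyond a <= 1 ppm window).
    """
    mC, mH = ISOTOPE_MASS["C"], ISOTOPE_MASS["H"]
    mN, mO, mS = ISOTOPE_MASS["N"], ISOTOPE_MASS["O"], ISOTOPE_MASS["S"]
    target = mz * charge + charge * PROTON_MASS
    tol_da = target * tol_ppm * 1e-6
    found = []
    for c in range(1, constraints.max_c + 1):
        if c * mC > target + tol_da:
            break
        for o in range(constraints.o_min, constraints.o_max + 1):
            if o > c * constraints.oc_max:
                break
            base_co = c * mC + o * mO
            if base_co > target + tol_da:
                break
            for n in range(0, constraints.max_n + 1):
                for s in range(0, constraints.max_s + 1):
                    base = base_co + n * mN + s * mS
                    h_mid = int((target - base) / mH)
                    for h in range(h_mid - 1, h_mid + 3):
                        if h < charge or h > constraints.max_h:
                            continue
                        if h > constraints.hc_max * c:
                            continue
                        if (h - n) % 2:          # even-electron parity
                            continue
                        dbe = c + 1 - (h - n) / 2
                        if dbe < 0:
                            continue
                        mass = base + h * mH
                        if abs(target - mass) <= tol_da:
                            found.append(MolecularFormula(c, h, n, o, s))
    return sorted(set(found))
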