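"""Internal mass recalibration against homologous CHO reference series.

FTICR spectra of natural organic matter carry dense CH2-homologous CHO
series; once a handful of abundant peaks are coarsely assigned, those
series provide hundreds of internal calibrants.  A low-order (linear in
m/z) ppm-error model is fitted to the matched calibrants and applied to
every peak, which removes systematic offset/drift and leaves the
white-noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .chem import MolecularFormula, mz_deprotonated
from .peaks import MassPeakList

__all__ = ["recalibrate", "bootstrap_reference_series", "CalibrationResult"]

MIN_REFERENCE_MATCHES = 5


@dataclass
class CalibrationResult:
    peak_list: MassPeakList
    applied: bool
    n_matched: int
    rms_ppm_before: float | None
    rms_ppm_after: float | None
    coefficients: tuple[float, float] | None  # err_ppm = a + b * mz
    message: str = ""


def _match_references(mz: np.ndarray,
                      reference: list[MolecularFormula],
                      window_ppm: float) -> tuple[np.ndarray, np.ndarray]:
    """Match observed m/z to reference [M-H]- masses within a ppm window.

    Returns (observed_mz, error_ppm) for unambiguous nearest matches.
    """
    ref_mz = np.array(sorted(mz_deprotonated(f) for f in reference))
    obs, err = [], []
    for m in mz:
        j = np.searchsorted(ref_mz, m)
        for k in (j - 1, j):
            if 0 <= k < len(ref_mz):
                e = (m - ref_mz[k]) / ref_mz[k] * 1e6
                if abs(e) <= window_ppm:
                    obs.append(m)
                    err.append(e)
                    break
    return np.asarray(obs), np.asarray(err)


def recalibrate(peak_list: MassPeakList,
                reference: list[MolecularFormula],
                window_ppm: float = 3.0,
                order: int = 1) -> CalibrationResult:
    """Fit and apply a linear-in-m/z ppm correction from reference matches.

    Refuses (returning the list unchanged, with a diagnostic) when fewer
    than five reference peaks match within the coarse window.  The
    residual RMS over the matched calibrants is recorded on the returned
    list and can only decrease relative to the raw RMS, least squares
    being what it is.
    """
    if order not in (0, 1):
        raise ValueError("only constant or linear corrections are supported")
    mz = peak_list.mz_array()
    obs, err = _match_references(mz, reference, window_ppm)
    if len(obs) < MIN_REFERENCE_MATCHES:
        return CalibrationResult(
            peak_list=peak_list, applied=False, n_matched=len(obs),
            rms_ppm_before=None, rms_ppm_after=None, coefficients=None,
            message=(f"only {len(obs)} reference matches within "
                     f"{window_ppm} ppm; need {MIN_REFERENCE_MATCHES}"))

    rms_before = float(np.sqrt(np.mean(err ** 2)))
    if order == 0:
        a, b = float(np.mean(err)), 0.0
    else:
        b, a = np.polyfit(obs, err, 1)
        a, b = float(a), float(b)

    predicted = a + b * obs
    resid = err - predicted
    rms_after = float(np.sqrt(np.mean(resid ** 2)))
    if rms_after > rms_before:  # cannot happen for LS with intercept
        a, b, rms_after = 0.0, 0.0, rms_before

    def correct(m: float) -> float:
        return m / (1.0 + (a + b * m) * 1e-6)

    new_peaks = [replace(p, mz=correct(p.mz)) for p in peak_list.peaks]
    corrected = peak_list.replace_peaks(
        new_peaks, calibration_state="calibrated",
        calibration_rms_ppm=rms_after)
    return CalibrationResult(
        peak_list=corrected, applied=True, n_matched=len(obs),
        rms_ppm_before=rms_before, rms_ppm_after=rms_after,
        coefficients=(a, b))


def bootstrap_reference_series(peak_list: MassPeakList,
                               window_ppm: float = 3.0,
                               top_n: int = 400,
                               min_series_length: int = 4) -> list[MolecularFormula]:
    """Derive a CHO calibrant set from the spectrum itself.

    The most abundant singly charged peaks are coarsely assigned to
    CHO-only formulae; unambiguous hits are grouped into CH2-homologous
    series (constant O count and DBE) and series with at least
    ``min_series_length`` members are returned as the reference set.
    """
    from .assign import AtomicConstraints, enumerate_candidates

    cho_box = AtomicConstraints(max_n=0, max_s=0)
    peaks = [p for p in peak_list.peaks
             if p.charge == 1 and not p.is_isotopologue]
    peaks = sorted(peaks, key=lambda p: p.intensity, reverse=True)[:top_n]

    series: dict[tuple[int, float], list[MolecularFormula]] = {}
    for p in peaks:
        cands = enumerate_candidates(p.mz, cho_box, tol_ppm=window_ppm)
        if len(cands) != 1:
            continue
        f = cands[0][0]
        series.setdefault((f.o, f.dbe), []).append(f)

    reference: list[MolecularFormula] = []
    for members in series.values():
        if len(members) >= min_series_length:
            reference.extend(members)
    return reference
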