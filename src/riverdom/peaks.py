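"""Mass peak lists: containers, S/N filtering and charge determination.

A peak list is the tabular output of a broadband FTICR acquisition:
(m/z, intensity, S/N) rows.  Charge state is inferred from the spacing
to the first 13C isotopologue satellite (dm = 1.0033548/z); isotopologue
peaks themselves are flagged so the monoisotopic peak alone enters
formula assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .chem import C13_C12_DELTA

__all__ = ["MassPeak", "MassPeakList", "filter_peaks", "determine_charge"]

#: Default acquisition window, Da.
MASS_WINDOW = (200.0, 800.0)


@dataclass(frozen=True)
class MassPeak:
    mz: float
    intensity: float
    snr: float
    charge: int = 1
    charge_defaulted: bool = False
    is_isotopologue: bool = False

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")


@dataclass
class MassPeakList:
    """An ordered, strictly mz-increasing collection of peaks for one sample."""

    sample_id: str
    peaks: list[MassPeak]
    calibration_state: str = "raw"  # raw | calibrated
    calibration_rms_ppm: float | None = None
    window: tuple[float, float] = MASS_WINDOW

    def __post_init__(self) -> None:
        mz = self.mz_array()
        if len(mz) > 1:
            rel = np.diff(mz) / mz[:-1]
            if np.any(np.diff(mz) <= 0):
                raise ValueError("peaks must be strictly increasing in m/z")
            if np.any(rel < 1e-9):
                raise ValueError("duplicate m/z within 1 ppb")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    def intensity_array(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)

    def snr_array(self) -> np.ndarray:
        return np.array([p.snr for p in self.peaks], dtype=float)

    def replace_peaks(self, peaks: Iterable[MassPeak], **changes) -> "MassPeakList":
        kwargs = dict(sample_id=self.sample_id,
                      calibration_state=self.calibration_state,
                      calibration_rms_ppm=self.calibration_rms_ppm,
                      window=self.window)
        kwargs.update(changes)
        return MassPeakList(peaks=sorted(peaks, key=lambda p: p.mz), **kwargs)


def filter_peaks(peak_list: MassPeakList, snr_min: float = 6.0) -> MassPeakList:
    """Keep peaks with S/N strictly greater than ``snr_min`` inside the window.

    The strict inequality follows the conventional "S/N > 6" mass-list
    criterion for DOM spectra.  Order is preserved; an empty result is
    allowed but warned about.
    """
    if not peak_list.peaks:
        raise ValueError("cannot filter an empty peak list")
    lo, hi = peak_list.window
    kept = [p for p in peak_list.peaks
            if p.snr > snr_min and lo <= p.mz <= hi]
    if not kept:
        warnings.warn(f"S/N filter removed every peak in {peak_list.sample_id}")
    return peak_list.replace_peaks(kept)


def determine_charge(peak_list: MassPeakList,
                     max_charge: int = 2,
                     spacing_tol_da: float = 8e-4,
                     min_ratio: float = 1e-3,
                     max_ratio: float = 0.75) -> MassPeakList:
    """Annotate charge states from 13C-satellite spacings.

    For each peak the list is searched for a heavier companion at
    ``mz + 1.0033548/z``; a companion with a plausible (sub-parent)
    intensity marks the peak as singly/multiply charged and the
    companion as an isotopologue.  Peaks with no detectable satellite
    default to the majority charge of the abundant peaks and carry a
    ``charge_defaulted`` flag.  Peaks with z != 1 and isotopologues are
    flagged here and excluded later by formula assignment.
    """
    mz = peak_list.mz_array()
    inten = peak_list.intensity_array()
    n = len(mz)
    charge = np.zeros(n, dtype=int)
    is_satellite = np.zeros(n, dtype=bool)

    order = np.argsort(inten)[::-1]  # resolve from the most abundant down
    for i in order:
        if is_satellite[i] or charge[i]:
            continue
        for z in range(1, max_charge + 1):
            target = mz[i] + C13_C12_DELTA / z
            j0 = np.searchsorted(mz, target - spacing_tol_da)
            j1 = np.searchsorted(mz, target + spacing_tol_da)
            for j in range(j0, j1):
                if j == i or is_satellite[j]:
                    continue
                ratio = inten[j] / inten[i] if inten[i] > 0 else np.inf
                if min_ratio <= ratio <= max_ratio:
                    charge[i] = z
                    is_satellite[j] = True
                    break
            if charge[i]:
                break

    resolved = charge[(charge > 0) & ~is_satellite]
    majority = int(np.bincount(resolved).argmax()) if resolved.size else 1
    defaulted = (charge == 0) & ~is_satellite
    charge[defaulted] = majority

    new_peaks = [replace(p, charge=int(charge[i]),
                         charge_defaulted=bool(defaulted[i]),
                         is_isotopologue=bool(is_satellite[i]))
                 for i, p in enumerate(peak_list.peaks)]
    return peak_list.replace_peaks(new_peaks)
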