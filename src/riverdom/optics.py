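"""CDOM optical descriptors: absorption coefficients, exponential
spectral slopes and slope ratio, and 1D fluorescence intensity ratios.

Absorption follows a = 2.303 * A / L (decadic optical density A over a
path of L metres); the CDOM spectrum is modelled as
a(lambda) = a(lambda0) * exp(-S (lambda - lambda0)) and S is fitted by
ordinary least squares in logarithmic coordinates.  The slope ratio
Sr = S(275-295)/S(350-400) is the standard Helms descriptor, inversely
related to DOM molecular weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AbsorptionSpectrum",
    "SlopeFit",
    "EEM",
    "absorption_coefficient",
    "spectral_slope",
    "slope_ratio",
    "specific_absorbance",
    "fir_descriptors",
]

LN10 = 2.303  # the conventional rounded factor of the a = 2.303 A / L formula


@dataclass
class AbsorptionSpectrum:
    """UV-Vis spectrum: wavelengths (nm), decadic optical density, path (m)."""

    wavelengths: np.ndarray
    optical_density: np.ndarray
    path_length_m: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.optical_density = np.asarray(self.optical_density, dtype=float)
        if self.wavelengths.shape != self.optical_density.shape:
            raise ValueError("wavelength and optical density grids differ")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.path_length_m <= 0:
            raise ValueError("path length must be positive")
        if np.any(self.optical_density < -0.005):
            raise ValueError("optical density below the -0.005 noise floor")

    def absorption(self) -> np.ndarray:
        """Napierian absorption coefficient a_lambda (1/m) on the grid."""
        return LN10 * self.optical_density / self.path_length_m


@dataclass
class SlopeFit:
    s: float              # spectral slope, 1/nm
    a_ref: float          # fitted absorption coefficient at lambda0, 1/m
    fit_range: tuple[float, float]
    r_squared: float
    n_points: int


def absorption_coefficient(spectrum: AbsorptionSpectrum,
                           wavelength: float,
                           interpolate: bool = False) -> float:
    """a_lambda = 2.303 * A_lambda / L at an on-grid wavelength (1/m).

    Off-grid wavelengths are refused unless ``interpolate=True`` asks
    for linear interpolation explicitly.
    """
    idx = np.nonzero(np.isclose(spectrum.wavelengths, wavelength,
                                rtol=0, atol=1e-9))[0]
    if idx.size:
        return float(LN10 * spectrum.optical_density[idx[0]]
                     / spectrum.path_length_m)
    if not interpolate:
        raise ValueError(
            f"{wavelength} nm is not on the grid; pass interpolate=True "
            "for linear interpolation")
    a = np.interp(wavelength, spectrum.wavelengths, spectrum.optical_density)
    return float(LN10 * a / spectrum.path_length_m)


def spectral_slope(spectrum: AbsorptionSpectrum,
                   fit_range: tuple[float, float],
                   min_points: int = 10) -> SlopeFit:
    """Exponential slope S over a wavelength range by log-linear OLS.

    Non-positive absorption values inside the range are dropped; fewer
    than ``min_points`` usable points is an error.  S is minus the slope
    of ln(a) on (lambda - lambda0) with lambda0 the range start, so the
    intercept is ln a(lambda0).
    """
    lo, hi = fit_range
    mask = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
    lam = spectrum.wavelengths[mask]
    a = spectrum.absorption()[mask]
    pos = a > 0
    lam, a = lam[pos], a[pos]
    if len(lam) < min_points:
        raise ValueError(
            f"only {len(lam)} positive points in {fit_range}; "
            f"need {min_points}")
    x = lam - lo
    y = np.log(a)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return SlopeFit(s=float(-slope), a_ref=float(np.exp(intercept)),
                    fit_range=fit_range, r_squared=r2, n_points=len(lam))


def slope_ratio(spectrum: AbsorptionSpectrum,
                uv_range: tuple[float, float] = (275.0, 295.0),
                vis_range: tuple[float, float] = (350.0, 400.0)) -> float:
    """Sr = S(275-295) / S(350-400); higher Sr, lower molecular weight."""
    s_uv = spectral_slope(spectrum, uv_range).s
    s_vis = spectral_slope(spectrum, vis_range).s
    if s_vis == 0:
        raise ZeroDivisionError("long-wavelength slope is zero")
    return s_uv / s_vis


def specific_absorbance(a254: float, c_org: float) -> float:
    """a254 normalized to organic-carbon content (efficient extinction
    coefficient), 1/m per mM."""
    if c_org <= 0:
        raise ValueError("c_org must be positive")
    return a254 / c_org


@dataclass
class EEM:
    """Excitation-emission matrix: intensity[emission, excitation].

    Scatter regions are masked as NaN (missing), never negative.
    """

    excitation: np.ndarray   # nm, columns
    emission: np.ndarray     # nm, rows
    intensity: np.ndarray    # shape (len(emission), len(excitation))
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.excitation = np.asarray(self.excitation, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (len(self.emission), len(self.excitation)):
            raise ValueError("intensity shape does not match the grids")
        if np.nanmin(self.intensity, initial=0.0) < 0:
            raise ValueError("EEM intensities must be non-negative or NaN")

    def mask_scatter(self, half_width_nm: float = 10.0) -> "EEM":
        """NaN-mask first- and second-order Rayleigh bands (+- half width)."""
        em = self.emission[:, None]
        ex = self.excitation[None, :]
        mask = (np.abs(em - ex) <= half_width_nm) | \
               (np.abs(em - 2 * ex) <= half_width_nm)
        out = self.intensity.copy()
        out[mask] = np.nan
        return EEM(self.excitation, self.emission, out, self.sample_id)

    def _ex_row(self, ex_nm: float) -> np.ndarray:
        j = np.nonzero(np.isclose(self.excitation, ex_nm))[0]
        if not j.size:
            raise ValueError(f"excitation {ex_nm} nm not on the grid")
        return self.intensity[:, j[0]]

    def _em_value(self, row: np.ndarray, em_nm: float) -> float:
        i = np.nonzero(np.isclose(self.emission, em_nm))[0]
        if not i.size:
            raise ValueError(f"emission {em_nm} nm not on the grid")
        return float(row[i[0]])


def fir_descriptors(eem: EEM) -> tuple[float, float]:
    """1D fluorescence intensity ratios from an EEM.

    ``f350_fmax``: emission at 350 nm over the emission maximum, both on
    the 280 nm excitation row — the protein-like (tryptophan-like)
    contribution.  ``f550_f375``: emission 550 nm over 375 nm at 350 nm
    excitation — the red-shift (humification) asymmetry ratio.
    """
    row280 = eem._ex_row(280.0)
    fmax = float(np.nanmax(row280))
    if fmax <= 0:
        raise ZeroDivisionError("zero emission maximum at 280 nm excitation")
    f350 = eem._em_value(row280, 350.0)
    row350 = eem._ex_row(350.0)
    f375 = eem._em_value(row350, 375.0)
    f550 = eem._em_value(row350, 550.0)
    if f375 == 0:
        raise ZeroDivisionError("zero emission at 375 nm")
    return f350 / fmax, f550 / f375
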