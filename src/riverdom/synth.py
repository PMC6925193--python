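"""Ground-truthed synthetic data with the statistical structure of a
south-to-north river transect.

The generator emulates the four input kinds of the analysis — molecular
ensembles, FTICR peak lists, UV-Vis absorption spectra, EEM stacks and
co-varying hydrochemistry — for a transect of stations whose dissolved
organic matter shifts from a humic/lignin-rich, amino-sugar-bearing
southern regime to an oxidized, tannin-dominated northern regime, with
a step at a confluence station.  Every generated object carries its
ground truth, so each downstream stage can be scored without reference
to external data.

Default magnitudes are calibrated to the printed ranges of transect
studies of large Arctic rivers: hydrolysable-tannin intensity density
rising from ~0.20 to ~0.45 south to north, low-oxidized lignins falling
from ~0.28 to ~0.11, peptide/amino-sugar density falling from ~0.06 to
~0, a shared formula core of ~1,600 compositions common to all
stations, organic carbon stepping from ~0.2 to ~1.1 mM at the
confluence, and three fluorophores with emission maxima near 350, 420
and 470 nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import (C13_ABUNDANCE_RATIO, C13_C12_DELTA, MolecularFormula,
                   PROTON_MASS, mz_deprotonated)
from .correlate import HydroRecord
from .optics import EEM, AbsorptionSpectrum
from .peaks import MassPeak, MassPeakList
from .profiles import CompoundClass, SampleEnsemble, classify

__all__ = [
    "TransectDesign",
    "FluorophoreSet",
    "EnsembleTruth",
    "PeakListTruth",
    "generate_ensembles",
    "generate_peaklist",
    "generate_absorption",
    "generate_eems",
    "generate_hydro",
    "generate_transect",
]

# Van Krevelen sampling boxes per class; H/C capped at 2.0 so sampled
# formulae stay inside the DOM assignment constraint box.
_CLASS_BOX = {
    CompoundClass.ALIPHATICS: ((0.05, 0.6), (1.6, 2.0)),
    CompoundClass.N_SATURATED: ((0.12, 0.6), (1.0, 2.0)),
    CompoundClass.LIGNIN_LOW_OX: ((0.12, 0.48), (0.72, 1.55)),
    CompoundClass.LIGNIN_OX: ((0.52, 0.95), (0.72, 1.55)),
    CompoundClass.TANNIN_CONDENSED: ((0.08, 0.48), (0.32, 0.68)),
    CompoundClass.TANNIN_HYDROLYSABLE: ((0.52, 0.95), (0.32, 0.68)),
    CompoundClass.CARBOHYDRATES: ((0.66, 0.95), (1.3, 2.0)),
}

#: Heteroatom family draw probabilities for classes that admit any family.
_FAMILY_P = {"CHO": 0.86, "CHON": 0.06, "CHOS": 0.07, "CHNOS": 0.01}


@dataclass
class TransectDesign:
    """Study design of the synthetic transect."""

    n_stations: int = 18
    confluence_index: int = 9
    shared_core_size: int = 1600
    unique_per_south_station: int = 50
    unique_intensity_fraction: float = 0.02
    south_weights: dict = field(default_factory=lambda: {
        CompoundClass.ALIPHATICS: 0.017,
        CompoundClass.N_SATURATED: 0.060,
        CompoundClass.LIGNIN_LOW_OX: 0.277,
        CompoundClass.LIGNIN_OX: 0.422,
        CompoundClass.TANNIN_CONDENSED: 0.009,
        CompoundClass.TANNIN_HYDROLYSABLE: 0.198,
        CompoundClass.CARBOHYDRATES: 0.016,
    })
    north_weights: dict = field(default_factory=lambda: {
        CompoundClass.ALIPHATICS: 0.002,
        CompoundClass.N_SATURATED: 0.002,
        CompoundClass.LIGNIN_LOW_OX: 0.114,
        CompoundClass.LIGNIN_OX: 0.417,
        CompoundClass.TANNIN_CONDENSED: 0.010,
        CompoundClass.TANNIN_HYDROLYSABLE: 0.445,
        CompoundClass.CARBOHYDRATES: 0.012,
    })
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.confluence_index < self.n_stations:
            raise ValueError("confluence index must split the transect")
        for w in (self.south_weights, self.north_weights):
            if any(v < 0 for v in w.values()) or sum(w.values()) <= 0:
                raise ValueError("class weights must be non-negative")

    def station_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_stations)]

    def gradient(self) -> np.ndarray:
        """Strictly increasing 0..1 south-to-north position, with a
        sigmoidal step at the confluence."""
        i = np.arange(self.n_stations, dtype=float)
        lin = i / (self.n_stations - 1)
        step = 1.0 / (1.0 + np.exp(-1.8 * (i - (self.confluence_index - 0.5))))
        g = 0.25 * lin + 0.75 * step
        return (g - g.min()) / (g.max() - g.min())

    def station_weights(self) -> pd.DataFrame:
        """Per-station normalized class mixture weights."""
        g = self.gradient()
        classes = list(self.south_weights)
        south = np.array([self.south_weights[c] for c in classes])
        north = np.array([self.north_weights[c] for c in classes])
        W = (1 - g)[:, None] * south[None, :] + g[:, None] * north[None, :]
        W = W / W.sum(axis=1, keepdims=True)
        return pd.DataFrame(W, index=self.station_ids(),
                            columns=[c.value for c in classes])


@dataclass
class EnsembleTruth:
    design: TransectDesign
    shared_core: set[MolecularFormula]
    unique_sets: dict[str, set[MolecularFormula]]
    class_density: pd.DataFrame        # stations x 8 labels, realized
    family_pct: pd.DataFrame           # stations x 4 families, by count
    gradient: np.ndarray


def _sample_formula(rng: np.random.Generator, target: CompoundClass,
                    family: str, mass_window=(205.0, 795.0),
                    max_tries: int = 200) -> MolecularFormula:
    """Rejection-sample one formula inside a class's Van Krevelen box."""
    (oc_lo, oc_hi), (hc_lo, hc_hi) = _CLASS_BOX[target]
    n = {"CHO": 0, "CHOS": 0}.get(family)
    if n is None:
        n = int(rng.integers(1, 3))
    s = 1 if family in ("CHOS", "CHNOS") else 0
    if target is CompoundClass.N_SATURATED and n == 0:
        n = 1
    if target is CompoundClass.ALIPHATICS:
        n = 0  # any N here would re-classify as N-saturated
    if n >= 1 and target in (CompoundClass.LIGNIN_LOW_OX,
                             CompoundClass.LIGNIN_OX):
        hc_hi = min(hc_hi, 0.98)  # keep clear of the N-saturated overlap
        if hc_hi <= hc_lo:
            n = 0
    for _ in range(max_tries):
        c = int(rng.integers(12, 33))
        oc = rng.uniform(oc_lo, oc_hi)
        hc = rng.uniform(hc_lo, hc_hi)
        o = int(np.clip(round(oc * c), 1, c))
        h = int(round(hc * c))
        if (h - n) % 2:  # even-electron parity
            h += 1 if rng.random() < 0.5 else -1
        if h < 1 or h > 2 * c:
            continue
        f = MolecularFormula(c, h, n, o, s)
        if f.dbe < 0 or f.oc_ratio > 1 or f.hc_ratio > 2:
            continue
        if classify(f) is not target:
            continue
        mz = f.monoisotopic_mass - PROTON_MASS
        if not mass_window[0] <= mz <= mass_window[1]:
            continue
        return f
    raise RuntimeError(f"could not sample a {target.value}/{family} formula")


def _draw_family(rng: np.random.Generator, target: CompoundClass) -> str:
    if target is CompoundClass.N_SATURATED:
        return "CHON" if rng.random() < 0.93 else "CHNOS"
    fams = list(_FAMILY_P)
    p = np.array([_FAMILY_P[f] for f in fams])
    return str(rng.choice(fams, p=p / p.sum()))


def _family_counts(target: CompoundClass, k: int) -> dict[str, int]:
    """Deterministic family allocation for k formulae of one class, so
    collision-resampling cannot skew the heteroatom shares."""
    if target is CompoundClass.N_SATURATED:
        probs = {"CHON": 0.93, "CHNOS": 0.07}
    else:
        probs = dict(_FAMILY_P)
    counts = {f: int(round(p * k)) for f, p in probs.items()}
    lead = max(probs, key=probs.get)
    counts[lead] += k - sum(counts.values())
    return {f: c for f, c in counts.items() if c > 0}


def generate_ensembles(design: TransectDesign | None = None
                       ) -> tuple[list[SampleEnsemble], EnsembleTruth]:
    """Build the transect's sample ensembles with exact ground truth.

    A shared core of formulae is present at every station; its
    within-class intensity shares are fixed log-normal shapes with small
    per-station jitter, while the class totals follow the designed
    south-to-north mixture weights — so the realized class densities
    track the design exactly up to the small unique-formula budget.
    Southern stations additionally carry planted station-unique formulae
    (lignin-like and amino-sugar-like, the "mire imprint").
    """
    design = design or TransectDesign()
    rng = np.random.default_rng(design.seed)
    classes = list(design.south_weights)
    W = design.station_weights()
    ids = design.station_ids()

    # allocate core formula counts per class from the transect-mean weights
    mean_w = W.mean(axis=0).to_numpy()
    counts = np.maximum(np.round(design.shared_core_size * mean_w), 10)
    counts = counts.astype(int)
    while counts.sum() != design.shared_core_size:
        k = int(np.argmax(counts)) if counts.sum() > design.shared_core_size \
            else int(np.argmin(counts))
        counts[k] += -1 if counts.sum() > design.shared_core_size else 1

    seen: set[MolecularFormula] = set()
    core_by_class: dict[CompoundClass, list[MolecularFormula]] = {}
    for cls, k in zip(classes, counts):
        members: list[MolecularFormula] = []
        for fam, kf in _family_counts(cls, int(k)).items():
            got = 0
            while got < kf:
                f = _sample_formula(rng, cls, fam)
                if f not in seen:
                    seen.add(f)
                    members.append(f)
                    got += 1
        core_by_class[cls] = members
    core_set = set(seen)

    base_share = {f: rng.lognormal(0.0, 1.0)
                  for members in core_by_class.values() for f in members}

    uniq_frac = design.unique_intensity_fraction
    unique_sets: dict[str, set[MolecularFormula]] = {}
    samples: list[SampleEnsemble] = []
    for i, sid in enumerate(ids):
        members: dict[MolecularFormula, float] = {}
        is_south = i < design.confluence_index
        core_scale = (1.0 - uniq_frac) if is_south and \
            design.unique_per_south_station else 1.0
        for cls in classes:
            w = float(W.loc[sid, cls.value]) * core_scale
            shares = np.array([base_share[f] * rng.lognormal(0.0, 0.25)
                               for f in core_by_class[cls]])
            shares = shares / shares.sum()
            for f, sh in zip(core_by_class[cls], shares):
                members[f] = w * sh
        uniques: set[MolecularFormula] = set()
        if is_south and design.unique_per_south_station:
            for _ in range(design.unique_per_south_station):
                cls = (CompoundClass.LIGNIN_LOW_OX if rng.random() < 0.6
                       else CompoundClass.N_SATURATED)
                fam = _draw_family(rng, cls)
                f = _sample_formula(rng, cls, fam)
                while f in seen:
                    f = _sample_formula(rng, cls, fam)
                seen.add(f)
                uniques.add(f)
            u_share = np.array([rng.lognormal(0.0, 0.7)
                                for _ in range(len(uniques))])
            u_share = uniq_frac * u_share / u_share.sum()
            for f, sh in zip(sorted(uniques), u_share):
                members[f] = sh
        unique_sets[sid] = uniques
        samples.append(SampleEnsemble(sample_id=sid, members=members))

    from .profiles import class_densities, stoichiometry_shares
    density = pd.DataFrame([class_densities(s) for s in samples])
    family = pd.DataFrame([stoichiometry_shares(s) for s in samples])
    truth = EnsembleTruth(design=design, shared_core=core_set,
                          unique_sets=unique_sets, class_density=density,
                          family_pct=family, gradient=design.gradient())
    return samples, truth


@dataclass
class PeakListTruth:
    """Per-peak provenance of a synthetic peak list (post m/z sorting)."""

    kind: list[str]                       # analyte | satellite | noise
    formula: list[MolecularFormula | None]
    true_mz: np.ndarray
    charge: np.ndarray


def generate_peaklist(ensemble: SampleEnsemble,
                      noise_ppm: float = 0.3,
                      offset_ppm: float = 1.5,
                      n_noise_peaks: int = 300,
                      seed: int = 0,
                      drift_ppm: float = 0.0,
                      fraction_z2: float = 0.0,
                      window: tuple[float, float] = (200.0, 800.0)
                      ) -> tuple[MassPeakList, PeakListTruth]:
    """Synthesize a raw FTICR peak list from an ensemble.

    Each formula contributes its [M-H]- peak with a systematic ppm
    offset (plus optional linear drift across the window) and Gaussian
    ppm noise, and a 13C isotopologue satellite at natural abundance.
    ``n_noise_peaks`` chemically meaningless peaks are added at S/N <= 6
    so the S/N filter removes them; analyte S/N is anchored so that
    every analyte peak survives the S/N > 6 screen.  Returns the raw
    list plus per-peak ground truth.
    """
    rng = np.random.default_rng(seed)
    lo, hi = window

    def ppm_error(true_mz: float) -> float:
        drift = drift_ppm * (true_mz - lo) / (hi - lo)
        return offset_ppm + drift + rng.normal(0.0, noise_ppm)

    rows = []  # (mz, intensity, kind, formula, true_mz, z)
    formulas = sorted(ensemble.members)
    intens = np.array([ensemble.members[f] for f in formulas]) * 1e9
    for f, inten in zip(formulas, intens):
        z = 2 if rng.random() < fraction_z2 else 1
        true_mz = mz_deprotonated(f, z)
        if not lo <= true_mz <= hi:
            continue
        mz = true_mz * (1.0 + ppm_error(true_mz) * 1e-6)
        rows.append((mz, inten, "analyte", f, true_mz, z))
        sat_true = true_mz + C13_C12_DELTA / z
        sat_mz = sat_true * (1.0 + ppm_error(sat_true) * 1e-6)
        sat_inten = inten * C13_ABUNDANCE_RATIO * f.c
        if sat_mz <= hi:
            rows.append((sat_mz, sat_inten, "satellite", f, sat_true, z))

    min_analyte = intens.min() if len(intens) else 1.0
    noise_floor = min_analyte / 8.0  # weakest analyte lands at S/N = 8
    for _ in range(n_noise_peaks):
        mz = rng.uniform(lo, hi)
        snr = rng.uniform(0.5, 5.9)
        rows.append((mz, snr * noise_floor, "noise", None, mz, 1))

    rows.sort(key=lambda r: r[0])
    dedup = []
    for r in rows:
        if dedup and (r[0] - dedup[-1][0]) / dedup[-1][0] < 1e-9:
            continue
        dedup.append(r)
    peaks = [MassPeak(mz=r[0], intensity=r[1],
                      snr=max(r[1] / noise_floor, 1e-3))
             for r in dedup]
    plist = MassPeakList(sample_id=ensemble.sample_id, peaks=peaks,
                         window=window)
    truth = PeakListTruth(kind=[r[2] for r in dedup],
                          formula=[r[3] for r in dedup],
                          true_mz=np.array([r[4] for r in dedup]),
                          charge=np.array([r[5] for r in dedup]))
    return plist, truth


def generate_absorption(a440_true: float = 2.0,
                        s_true: float = 0.016,
                        noise_frac: float = 0.0,
                        seed: int = 0,
                        path_length_m: float = 0.01,
                        grid: tuple[float, float, float] = (200.0, 600.0, 1.0),
                        second: tuple[float, float] | None = None,
                        sample_id: str = "") -> AbsorptionSpectrum:
    """Synthetic CDOM absorption spectrum.

    Single exponential ``a = a440 exp(-s (lambda - 440))`` by default;
    ``second=(fraction, s2)`` adds a shallower component so the
    UV and visible spectral slopes differ.  Multiplicative Gaussian
    noise of relative scale ``noise_frac``; optical density follows from
    a = 2.303 A / L.
    """
    rng = np.random.default_rng(seed)
    lam = np.arange(grid[0], grid[1] + grid[2] / 2, grid[2])
    if second is None:
        a = a440_true * np.exp(-s_true * (lam - 440.0))
    else:
        frac, s2 = second
        a = a440_true * ((1 - frac) * np.exp(-s_true * (lam - 440.0))
                         + frac * np.exp(-s2 * (lam - 440.0)))
    if noise_frac:
        a = a * (1.0 + rng.normal(0.0, noise_frac, lam.shape))
    od = np.maximum(a, 0.0) * path_length_m / 2.303
    return AbsorptionSpectrum(wavelengths=lam, optical_density=od,
                              path_length_m=path_length_m,
                              sample_id=sample_id)


@dataclass
class FluorophoreSet:
    """Gaussian excitation/emission band models of the fluorophores,
    ordered by emission maximum, plus per-sample true scores."""

    bands: list[tuple[float, float, float, float]] = field(
        default_factory=lambda: [
            (280.0, 18.0, 350.0, 22.0),   # protein-like (tryptophan-like)
            (320.0, 25.0, 420.0, 40.0),   # humic-like
            (360.0, 30.0, 470.0, 50.0),   # red-shifted humic-like
        ])
    scores: np.ndarray = field(
        default_factory=lambda: np.array([[1.0, 1.0, 1.0]]))

    @classmethod
    def for_transect(cls, design: TransectDesign) -> "FluorophoreSet":
        """Scores following the transect: protein-like fluorescence
        falls northward, humic components rise."""
        z = design.gradient()
        scores = np.column_stack([1.6 - 1.3 * z,
                                  0.8 + 1.4 * z,
                                  0.5 + 1.0 * z])
        return cls(scores=scores)

    def profiles(self, excitation: np.ndarray, emission: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
        ex_prof = np.column_stack([
            np.exp(-0.5 * ((excitation - cx) / sx) ** 2)
            for cx, sx, _, _ in self.bands])
        em_prof = np.column_stack([
            np.exp(-0.5 * ((emission - cm) / sm) ** 2)
            for _, _, cm, sm in self.bands])
        return ex_prof, em_prof


def generate_eems(fluorophores: FluorophoreSet | None = None,
                  noise_frac: float = 0.0,
                  seed: int = 0,
                  excitation: np.ndarray | None = None,
                  emission: np.ndarray | None = None,
                  sample_ids: list[str] | None = None
                  ) -> tuple[list[EEM], dict]:
    """Trilinear EEM stack: outer products of the fluorophore bands
    weighted by the true scores, plus additive Gaussian noise (clipped
    at zero).  Returns the EEMs and the ground truth (profiles on the
    grids plus the score matrix)."""
    fluorophores = fluorophores or FluorophoreSet()
    rng = np.random.default_rng(seed)
    ex = excitation if excitation is not None \
        else np.arange(280.0, 411.0, 10.0)
    em = emission if emission is not None else np.arange(300.0, 701.0, 5.0)
    ex_prof, em_prof = fluorophores.profiles(ex, em)
    scores = np.asarray(fluorophores.scores, dtype=float)
    ids = sample_ids or [f"S{i + 1:02d}" for i in range(len(scores))]
    eems = []
    for sid, s in zip(ids, scores):
        X = np.einsum("r,jr,kr->jk", s, em_prof, ex_prof)
        if noise_frac:
            X = X + rng.normal(0.0, noise_frac * X.max(), X.shape)
        eems.append(EEM(excitation=ex, emission=em,
                        intensity=np.maximum(X, 0.0), sample_id=sid))
    truth = {"ex_profiles": ex_prof, "em_profiles": em_prof,
             "scores": scores}
    return eems, truth


def generate_hydro(design: TransectDesign,
                   ensembles_truth: EnsembleTruth,
                   seed: int = 0,
                   noise_frac: float = 0.03) -> list[HydroRecord]:
    """Hydrochemistry co-varying with the molecular gradient.

    Every parameter except temperature is a monotone function of the
    station's realized hydrolysable-tannin (oxidized-class) density plus
    noise scaled by ``noise_frac`` — organic carbon steps from ~0.2 mM
    south to ~1.1 mM north of the confluence and the carbonate-system
    parameters inter-correlate with it (Spearman > 0.7 by design).
    Temperature declines northward along the station index.
    """
    if len(ensembles_truth.class_density) != design.n_stations:
        raise ValueError("truth and design station counts differ")
    rng = np.random.default_rng(seed)
    d_ox = ensembles_truth.class_density[
        CompoundClass.TANNIN_HYDROLYSABLE.value].to_numpy()
    z = (d_ox - d_ox.min()) / (d_ox.max() - d_ox.min())
    lin = np.arange(design.n_stations) / (design.n_stations - 1)
    k = noise_frac / 0.03 if noise_frac else 0.0

    def jitter(scale: float) -> np.ndarray:
        return rng.normal(0.0, scale * k, design.n_stations) if k else 0.0

    c_org = np.maximum(0.2 + 0.9 * z + jitter(0.02), 0.01)
    records = []
    vals = {
        "temperature": 16.0 - 9.0 * lin + jitter(0.3),
        "salinity": np.maximum(0.04 + 0.20 * z + jitter(0.005), 0.0),
        "ph": 7.0 + 1.0 * z + jitter(0.03),
        "alkalinity": np.maximum(900.0 + 1600.0 * z + jitter(30.0), 0.0),
        "co2": np.maximum(60.0 + 120.0 * z + jitter(4.0), 0.0),
        "si": np.maximum(35.0 + 55.0 * z + jitter(2.0), 0.0),
        "c_org": c_org,
        "a254": np.maximum(46.0 * c_org * (1.0 + jitter(0.03)), 0.0),
    }
    vals["hco3"] = np.maximum(0.95 * vals["alkalinity"] + jitter(20.0), 0.0)
    for i, sid in enumerate(design.station_ids()):
        records.append(HydroRecord(
            station_id=sid,
            temperature=float(np.asarray(vals["temperature"])[i]),
            salinity=float(np.asarray(vals["salinity"])[i]),
            ph=float(np.asarray(vals["ph"])[i]),
            alkalinity=float(np.asarray(vals["alkalinity"])[i]),
            hco3=float(np.asarray(vals["hco3"])[i]),
            co2=float(np.asarray(vals["co2"])[i]),
            si=float(np.asarray(vals["si"])[i]),
            c_org=float(np.asarray(vals["c_org"])[i]),
            a254=float(np.asarray(vals["a254"])[i])))
    return records


@dataclass
class TransectData:
    """One fully synthesized transect: all four input kinds plus truth."""

    design: TransectDesign
    ensembles: list[SampleEnsemble]
    ensemble_truth: EnsembleTruth
    peaklists: list[MassPeakList]
    peaklist_truths: list[PeakListTruth]
    absorption: list[AbsorptionSpectrum]
    eems: list[EEM]
    eem_truth: dict
    hydro: list[HydroRecord]


def generate_transect(design: TransectDesign | None = None,
                      noise_ppm: float = 0.3,
                      offset_ppm: float = 1.5,
                      eem_noise_frac: float = 0.02,
                      hydro_noise_frac: float = 0.03,
                      n_noise_peaks: int = 300) -> TransectData:
    """Synthesize every input kind for one transect under one seed."""
    design = design or TransectDesign()
    ensembles, truth = generate_ensembles(design)
    rng = np.random.default_rng(design.seed + 1)
    peaklists, pl_truths = [], []
    for e in ensembles:
        pl, t = generate_peaklist(e, noise_ppm=noise_ppm,
                                  offset_ppm=offset_ppm,
                                  n_noise_peaks=n_noise_peaks,
                                  seed=int(rng.integers(2 ** 31)))
        peaklists.append(pl)
        pl_truths.append(t)
    z = design.gradient()
    absorption = [
        generate_absorption(a440_true=0.5 + 2.0 * zi,
                            s_true=0.030, second=(0.70 - 0.35 * zi, 0.012),
                            noise_frac=0.005,
                            seed=int(rng.integers(2 ** 31)),
                            sample_id=sid)
        for zi, sid in zip(z, design.station_ids())]
    eems, eem_truth = generate_eems(
        FluorophoreSet.for_transect(design), noise_frac=eem_noise_frac,
        seed=int(rng.integers(2 ** 31)),
        sample_ids=design.station_ids())
    hydro = generate_hydro(design, truth,
                           seed=int(rng.integers(2 ** 31)),
                           noise_frac=hydro_noise_frac)
    return TransectData(design=design, ensembles=ensembles,
                        ensemble_truth=truth, peaklists=peaklists,
                        peaklist_truths=pl_truths, absorption=absorption,
                        eems=eems, eem_truth=eem_truth, hydro=hydro)
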