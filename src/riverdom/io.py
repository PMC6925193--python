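"""Delimited-text readers and writers for every tabular format the
pipeline touches, plus the YAML pipeline configuration.

All formats are plain text: peak lists (mz / intensity / snr TSV),
hydrochemistry station tables, two-column absorption spectra (with the
path length in a comment header), and EEM matrices with an excitation
header row and emission-labelled rows.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .correlate import HYDRO_PARAMETERS, HydroRecord
from .optics import EEM, AbsorptionSpectrum
from .peaks import MassPeak, MassPeakList

__all__ = [
    "read_peaklist", "write_peaklist",
    "read_hydro_table", "write_hydro_table",
    "read_absorption", "write_absorption",
    "read_eem", "write_eem",
]

_MZ_FMT = "%.7f"


def write_peaklist(peak_list: MassPeakList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sample_id={peak_list.sample_id}\n")
        fh.write(f"# calibration_state={peak_list.calibration_state}\n")
        if peak_list.calibration_rms_ppm is not None:
            fh.write(f"# calibration_rms_ppm="
                     f"{peak_list.calibration_rms_ppm:.4f}\n")
        fh.write("mz\tintensity\tsnr\tcharge\n")
        for p in peak_list.peaks:
            fh.write(f"{p.mz:.7f}\t{p.intensity:.6g}\t{p.snr:.4f}"
                     f"\t{p.charge}\n")


def read_peaklist(path: str | Path, sample_id: str | None = None
                  ) -> MassPeakList:
    """Read a delimited peak list; the mz/intensity/snr header is required."""
    meta = {}
    lines = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            if "=" in line:
                k, v = line.lstrip("# ").split("=", 1)
                meta[k.strip()] = v.strip()
        elif line.strip():
            lines.append(line)
    df = pd.read_csv(_io.StringIO("\n".join(lines)), sep=r"[\t,;]",
                     engine="python")
    required = {"mz", "intensity", "snr"}
    if not required <= set(df.columns):
        raise ValueError(f"peak list must have columns {sorted(required)}")
    peaks = [MassPeak(mz=float(r.mz), intensity=float(r.intensity),
                      snr=float(r.snr),
                      charge=int(getattr(r, "charge", 1)))
             for r in df.itertuples(index=False)]
    rms = meta.get("calibration_rms_ppm")
    return MassPeakList(
        sample_id=sample_id or meta.get("sample_id", Path(path).stem),
        peaks=sorted(peaks, key=lambda p: p.mz),
        calibration_state=meta.get("calibration_state", "raw"),
        calibration_rms_ppm=float(rms) if rms else None)


def write_hydro_table(records: list[HydroRecord], path: str | Path) -> None:
    df = pd.DataFrame([r.as_series() for r in records])
    df.index.name = "station_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_hydro_table(path: str | Path) -> list[HydroRecord]:
    df = pd.read_csv(path, sep="\t", index_col="station_id")
    missing = set(HYDRO_PARAMETERS) - set(df.columns)
    if missing:
        raise ValueError(f"hydrochemistry table lacks columns {sorted(missing)}")
    return [HydroRecord(station_id=str(idx),
                        **{p: float(row[p]) for p in HYDRO_PARAMETERS})
            for idx, row in df.iterrows()]


def write_absorption(spectrum: AbsorptionSpectrum, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sample_id={spectrum.sample_id}\n")
        fh.write(f"# path_length_m={spectrum.path_length_m}\n")
        fh.write("wavelength_nm\toptical_density\n")
        for lam, od in zip(spectrum.wavelengths, spectrum.optical_density):
            fh.write(f"{lam:.1f}\t{od:.8g}\n")


def read_absorption(path: str | Path) -> AbsorptionSpectrum:
    meta = {}
    lines = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            k, v = line.lstrip("# ").split("=", 1)
            meta[k.strip()] = v.strip()
        elif line.strip():
            lines.append(line)
    df = pd.read_csv(_io.StringIO("\n".join(lines)), sep="\t")
    return AbsorptionSpectrum(
        wavelengths=df["wavelength_nm"].to_numpy(float),
        optical_density=df["optical_density"].to_numpy(float),
        path_length_m=float(meta.get("path_length_m", 0.01)),
        sample_id=meta.get("sample_id", Path(path).stem))


def write_eem(eem: EEM, path: str | Path) -> None:
    """Matrix text: emission rows x excitation columns, excitation header."""
    with open(path, "w") as fh:
        fh.write(f"# sample_id={eem.sample_id}\n")
        fh.write("emission_nm\t" + "\t".join(f"{x:.1f}" for x in
                                             eem.excitation) + "\n")
        for em, row in zip(eem.emission, eem.intensity):
            cells = "\t".join("nan" if np.isnan(v) else f"{v:.8g}"
                              for v in row)
            fh.write(f"{em:.1f}\t{cells}\n")


def read_eem(path: str | Path) -> EEM:
    sample_id = Path(path).stem
    lines = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            if "sample_id=" in line:
                sample_id = line.split("=", 1)[1].strip()
        elif line.strip():
            lines.append(line)
    header = lines[0].split("\t")
    excitation = np.array([float(x) for x in header[1:]])
    emission, rows = [], []
    for line in lines[1:]:
        cells = line.split("\t")
        emission.append(float(cells[0]))
        rows.append([float(c) for c in cells[1:]])
    return EEM(excitation=excitation, emission=np.array(emission),
               intensity=np.array(rows), sample_id=sample_id)
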