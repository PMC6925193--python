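"""End-to-end transect pipeline: peak processing, molecular profiling,
optics and correlation mapping, with delimited-text reports.

The pipeline consumes either on-disk inputs (peak lists, hydrochemistry
table, absorption spectra, EEMs) or, by default, a fully synthetic
transect generated under the configured seed.  Stages run in the fixed
order filter -> charge -> calibrate -> assign -> profile ->
common/unique -> optics -> correlations; any stage failure aborts with
the stage and sample named.  Outputs are deterministic for a given
configuration and seed, down to the byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .assign import AtomicConstraints, assign_formulae
from .calibration import bootstrap_reference_series, recalibrate
from .correlate import (CorrelationMap, hydro_matrix, select_parameters,
                        spearman_map, vk_overlay)
from .optics import fir_descriptors, slope_ratio, spectral_slope
from .parafac import TrilinearModel, component_ratios, fit_trilinear
from .peaks import determine_charge, filter_peaks
from .profiles import (SampleEnsemble, class_densities, common_formulae,
                       number_averaged, unique_formulae)
from .synth import TransectDesign, generate_transect

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All pipeline thresholds, each with its conventional default.

    snr_min: mass-list S/N threshold (strict >), default 6.
    tol_ppm: formula assignment tolerance after calibration, 0.5 ppm.
    calib_window_ppm: coarse window for calibrant matching, 3 ppm.
    alpha: Spearman significance level, 0.05.
    min_significant: parameter-selection count screen (strict >), 200.
    r_threshold: strong-correlation highlight threshold (strict >), 0.7.
    exclude_stations: station ids dropped before correlation analysis
        (outlier policy is configuration, not code).
    """

    seed: int = 0
    snr_min: float = 6.0
    tol_ppm: float = 0.5
    calib_window_ppm: float = 3.0
    alpha: float = 0.05
    min_significant: int = 200
    r_threshold: float = 0.7
    n_components: int = 3
    exclude_stations: list = field(default_factory=list)
    constraints: dict = field(default_factory=dict)
    design: dict = field(default_factory=dict)
    require_hydro: bool = True
    peaklist_dir: str | None = None
    hydro_table: str | None = None
    absorption_dir: str | None = None
    eem_dir: str | None = None
    outdir: str = "riverdom_out"

    def atomic_constraints(self) -> AtomicConstraints:
        return AtomicConstraints(**self.constraints)

    def transect_design(self) -> TransectDesign:
        return TransectDesign(seed=self.seed, **self.design)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        """Hash of the analysis-relevant configuration (the output
        location does not affect results and is excluded, so reruns
        into different directories stamp identical tables)."""
        payload = asdict(self)
        payload.pop("outdir", None)
        return hashlib.sha256(
            yaml.safe_dump(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineReport:
    config: PipelineConfig
    ensembles: list[SampleEnsemble]
    hydro: list
    table2: pd.DataFrame
    table3: pd.DataFrame
    common: set
    unique: dict
    optics_table: pd.DataFrame
    model: TrilinearModel | None
    ratios: pd.DataFrame | None
    correlation_map: CorrelationMap | None
    selected_parameters: list[str]
    overlays: dict[str, pd.DataFrame]
    hydro_corr: pd.DataFrame | None
    log: list[str]


class StageError(RuntimeError):
    def __init__(self, stage: str, sample: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {sample!r}: {cause}")
        self.stage, self.sample = stage, sample


def _stage(log: list[str], stage: str, sample: str, fn):
    try:
        return fn()
    except Exception as exc:  # noqa: BLE001 - abort naming the stage
        raise StageError(stage, sample, exc) from exc


def run_pipeline(config: PipelineConfig | None = None,
                 write: bool = True) -> PipelineReport:
    """Run the full transect analysis and (optionally) write reports."""
    config = config or PipelineConfig()
    log: list[str] = [f"config_hash={config.digest()}",
                      f"seed={config.seed}"]
    rng_note = f"python={sys.version.split()[0]} numpy={np.__version__}"
    log.append(rng_note)

    # ---- inputs -----------------------------------------------------
    if config.peaklist_dir:
        paths = sorted(Path(config.peaklist_dir).glob("*.tsv"))
        if not paths:
            raise StageError("inputs", config.peaklist_dir,
                             FileNotFoundError("no peak lists found"))
        peaklists = [rio.read_peaklist(p) for p in paths]
        absorption = ([rio.read_absorption(p) for p in
                       sorted(Path(config.absorption_dir).glob("*.tsv"))]
                      if config.absorption_dir else [])
        eems = ([rio.read_eem(p) for p in
                 sorted(Path(config.eem_dir).glob("*.tsv"))]
                if config.eem_dir else [])
        if config.hydro_table:
            hydro = rio.read_hydro_table(config.hydro_table)
        elif config.require_hydro:
            raise StageError("correlations", "hydro",
                             FileNotFoundError("hydrochemistry table missing"))
        else:
            hydro = []
        log.append(f"inputs: {len(peaklists)} peak lists from disk")
    else:
        data = generate_transect(config.transect_design())
        peaklists, absorption = data.peaklists, data.absorption
        eems, hydro = data.eems, data.hydro
        log.append(f"inputs: synthetic transect of {len(peaklists)} stations")

    # ---- peak processing and assignment -----------------------------
    constraints = config.atomic_constraints()
    ensembles: list[SampleEnsemble] = []
    for pl in peaklists:
        sid = pl.sample_id
        filtered = _stage(log, "filter", sid,
                          lambda: filter_peaks(pl, config.snr_min))
        charged = _stage(log, "charge", sid,
                         lambda: determine_charge(filtered))
        reference = _stage(log, "calibrate", sid,
                           lambda: bootstrap_reference_series(
                               charged, config.calib_window_ppm))
        calib = _stage(log, "calibrate", sid,
                       lambda: recalibrate(charged, reference,
                                           config.calib_window_ppm))
        assigned = _stage(log, "assign", sid,
                          lambda: assign_formulae(
                              calib.peak_list, constraints, config.tol_ppm,
                              require_calibrated=calib.applied))
        ensembles.append(SampleEnsemble.from_assignment(assigned))
        rms = (f"{calib.rms_ppm_after:.3f}" if calib.applied else "n/a")
        log.append(f"{sid}: {len(pl)} raw -> {len(filtered)} filtered; "
                   f"calibration rms {rms} ppm; "
                   f"{len(assigned)} assigned, "
                   f"{assigned.n_ambiguous} ambiguous, "
                   f"{assigned.n_unassigned} unassigned")

    # ---- molecular profiles -----------------------------------------
    table2 = pd.DataFrame([number_averaged(e) for e in ensembles])
    table3 = pd.DataFrame([class_densities(e) for e in ensembles])
    kept = [e for e in ensembles
            if e.sample_id not in set(config.exclude_stations)]
    common = _stage(log, "profile", "all",
                    lambda: common_formulae(kept))
    unique = _stage(log, "profile", "all",
                    lambda: unique_formulae(ensembles))
    log.append(f"common formulae (n={len(common)}) over {len(kept)} stations")

    # ---- optics ------------------------------------------------------
    optics_rows = []
    for spec in absorption:
        row = {"sample_id": spec.sample_id,
               "s_275_295": spectral_slope(spec, (275.0, 295.0)).s,
               "s_350_400": spectral_slope(spec, (350.0, 400.0)).s,
               "sr": slope_ratio(spec)}
        optics_rows.append(row)
    optics_table = pd.DataFrame(optics_rows)
    if eems:
        firs = [fir_descriptors(e.mask_scatter()) for e in eems]
        fir_df = pd.DataFrame(firs, columns=["f350_fmax", "f550_f375"])
        fir_df.insert(0, "sample_id", [e.sample_id for e in eems])
        optics_table = (fir_df if optics_table.empty else
                        optics_table.merge(fir_df, on="sample_id",
                                           how="outer"))
    model = ratios = None
    if len(eems) >= 6:
        model = _stage(log, "optics", "eem-stack",
                       lambda: fit_trilinear(eems, config.n_components,
                                             seed=config.seed))
        log.append(f"trilinear model: {model.n_components} components, "
                   f"R2={model.variance_explained:.4f}, "
                   f"{model.n_iterations} iterations")
        if model.n_components == 3:
            ratios = component_ratios(model)

    # ---- correlations ------------------------------------------------
    cmap = None
    selected: list[str] = []
    overlays: dict[str, pd.DataFrame] = {}
    hydro_corr = None
    if hydro:
        keep_ids = {e.sample_id for e in kept}
        hkept = [h for h in hydro if h.station_id in keep_ids]
        cmap = _stage(log, "correlations", "all",
                      lambda: spearman_map(kept, hkept, common,
                                           config.alpha))
        selected = select_parameters(cmap, config.min_significant)
        overlays = {p: vk_overlay(cmap, p, config.r_threshold)
                    for p in selected}
        hydro_corr = hydro_matrix(hkept)
        log.append(f"selected parameters (> {config.min_significant} "
                   f"significant): {', '.join(selected) or 'none'}")

    report = PipelineReport(config=config, ensembles=ensembles, hydro=hydro,
                            table2=table2, table3=table3, common=common,
                            unique=unique, optics_table=optics_table,
                            model=model, ratios=ratios,
                            correlation_map=cmap,
                            selected_parameters=selected,
                            overlays=overlays, hydro_corr=hydro_corr,
                            log=log)
    if write:
        _write_report(report)
    return report


def _write_report(report: PipelineReport) -> None:
    out = Path(report.config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"# config_hash={report.config.digest()}\n"

    def dump(df: pd.DataFrame, name: str, fmt: str, index: bool = True,
             index_label: str | None = "sample_id") -> None:
        with open(out / name, "w") as fh:
            fh.write(stamp)
            df.to_csv(fh, sep="\t", float_format=fmt, index=index,
                      index_label=index_label if index else None)

    dump(report.table2, "number_averaged.tsv", "%.2f")
    dump(report.table3, "class_densities.tsv", "%.3f")
    if not report.optics_table.empty:
        dump(report.optics_table, "optics.tsv", "%.5g", index=False)
    if report.ratios is not None:
        dump(report.ratios, "component_ratios.tsv", "%.2f")
    if report.model is not None:
        m = report.model
        load = pd.DataFrame(
            np.vstack([np.column_stack([m.emission, m.em_loadings]),
                       ]),
            columns=["emission_nm"] + [f"c{i+1}_em"
                                       for i in range(m.n_components)])
        dump(load, "parafac_emission_loadings.tsv", "%.5g", index=False)
        exload = pd.DataFrame(
            np.column_stack([m.excitation, m.ex_loadings]),
            columns=["excitation_nm"] + [f"c{i+1}_ex"
                                         for i in range(m.n_components)])
        dump(exload, "parafac_excitation_loadings.tsv", "%.5g", index=False)
        scores = pd.DataFrame(m.scores, index=m.sample_ids,
                              columns=[f"c{i+1}" for i in
                                       range(m.n_components)])
        dump(scores, "parafac_scores.tsv", "%.5g")
    for param, overlay in report.overlays.items():
        dump(overlay, f"overlay_{param}.tsv", "%.4f", index=False)
    if report.hydro_corr is not None:
        dump(report.hydro_corr, "hydro_correlation_matrix.tsv", "%.3f",
             index_label="parameter")
    (out / "run_log.txt").write_text("\n".join(report.log) + "\n")
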