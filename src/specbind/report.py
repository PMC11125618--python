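"""Combined study runner: execute every available stage and collate a report.

``run_full_study`` takes a structured configuration (a mapping, or a path to
a YAML file of the same shape) naming input files per stage, executes the
stages that have inputs in the fixed order quenching -> FRET -> thermo ->
FTIR -> EEM, and returns a ``StudyReport`` whose every number is the output
of exactly one library operation. Stages without inputs are skipped with a
notice; a failing stage is recorded in the report's error list rather than
aborting the rest.

Configuration shape (all sections optional)::

    seed: 0
    tau0_s: 1.0e-8
    k2: 0.6667
    refractive_index: 1.34
    quantum_yield: 0.15
    quenching:
      titrations:                 # one file per temperature
        "293": path/to/titration_293.csv
        "298": path/to/titration_298.csv
    fret:
      emission: path/to/emission.csv
      absorption: path/to/absorption.csv
      concentration_mol_L: 1.0e-5
      path_length_cm: 1.0
      f0: 1000.0
      f: 870.0
    ligands:
      - {name: PFBS, formula: C4F9O3S, binding_energy_kcal: -5.196}
    ftir:
      spectrum: path/to/ftir.csv
    eem:
      reference: path/to/eem_free.csv
      treated: path/to/eem_complex.csv
      scatter_half_width_nm: 15.0

The report serializes to JSON losslessly (``to_json`` / ``from_json``); the
provenance block records input digests, the configuration and the package
version, so identical inputs give byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__, eem, fret, ftir, quenching, thermo
from .errors import SpecbindError
from .io import (
    AbsorptionSpectrum,
    AxisKind,
    SignalKind,
    read_eem,
    read_spectrum,
    read_titration,
)

logger = logging.getLogger("specbind")

__all__ = ["StudyReport", "run_full_study", "load_config"]


@dataclass
class StudyReport:
    quenching_by_T: dict[str, Any] = field(default_factory=dict)
    fret: dict[str, Any] | None = None
    thermo: dict[str, Any] | None = None
    ligands: list[dict[str, Any]] = field(default_factory=list)
    secondary_structure: dict[str, Any] | None = None
    eem_shifts: list[dict[str, Any]] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StudyReport":
        return cls(**json.loads(text))

    def write(self, path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")


def load_config(source) -> dict:
    """Accept a mapping as-is, or read a YAML file path."""
    if isinstance(source, Mapping):
        return dict(source)
    text = Path(source).read_text(encoding="utf-8")
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise SpecbindError(f"config {source} did not parse to a mapping")
    return cfg


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _require_file(path, stage: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise SpecbindError(f"{stage}: input file not found: {p}")
    return p


def _asdict_enumsafe(obj) -> dict[str, Any]:
    def convert(v):
        if isinstance(v, dict):
            return {k: convert(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [convert(x) for x in v]
        if hasattr(v, "value") and not isinstance(v, (int, float)):
            return v.value
        if isinstance(v, float):
            return float(v)  # strip numpy scalar types
        return v

    return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}


def run_full_study(config) -> StudyReport:
    """Execute every configured stage in order and collate the results."""
    cfg = load_config(config)
    report = StudyReport()
    digests: dict[str, str] = {}
    tau0 = float(cfg.get("tau0_s", quenching.DEFAULT_TAU0_S))

    # --- quenching (per temperature) -> feeds thermo --------------------
    ka_by_T: dict[float, float] = {}
    qcfg = cfg.get("quenching")
    if qcfg and qcfg.get("titrations"):
        for t_key, path in sorted(qcfg["titrations"].items(), key=lambda kv: float(kv[0])):
            temp = float(t_key)
            try:
                p = _require_file(path, "quenching")
                digests[str(p)] = _digest(p)
                series = read_titration(p, temperature_K=temp)
                result = quenching.analyze_titration(series, tau0=tau0)
                report.quenching_by_T[f"{temp:g}"] = _asdict_enumsafe(result)
                if result.Ka is not None:
                    ka_by_T[temp] = result.Ka
            except SpecbindError as exc:
                report.errors.append(f"quenching @ {temp:g} K: {exc}")
                logger.error("quenching stage failed at %g K: %s", temp, exc)
    else:
        report.skipped.append("quenching: no titration files configured")

    # --- FRET -----------------------------------------------------------
    fcfg = cfg.get("fret")
    if fcfg:
        try:
            em_path = _require_file(fcfg["emission"], "fret")
            ab_path = _require_file(fcfg["absorption"], "fret")
            digests[str(em_path)] = _digest(em_path)
            digests[str(ab_path)] = _digest(ab_path)
            emission = read_spectrum(em_path, AxisKind.WAVELENGTH_NM, SignalKind.FLUORESCENCE_EMISSION)
            ab = read_spectrum(ab_path, AxisKind.WAVELENGTH_NM, SignalKind.UV_VIS_ABSORBANCE)
            absorption = AbsorptionSpectrum(
                axis=ab.axis,
                intensity=ab.intensity,
                axis_kind=ab.axis_kind,
                signal_kind=ab.signal_kind,
                molar_concentration=float(fcfg.get("concentration_mol_L", 1.0e-5)),
                path_length_cm=float(fcfg.get("path_length_cm", 1.0)),
            )
            result = fret.fret_analysis(
                emission,
                absorption,
                F=float(fcfg["f"]),
                F0=float(fcfg["f0"]),
                K2=float(cfg.get("k2", fret.DEFAULT_K2)),
                N=float(cfg.get("refractive_index", fret.DEFAULT_REFRACTIVE_INDEX)),
                phi=float(cfg.get("quantum_yield", fret.DEFAULT_QUANTUM_YIELD)),
            )
            report.fret = _asdict_enumsafe(result)
        except (SpecbindError, KeyError) as exc:
            report.errors.append(f"fret: {exc}")
            logger.error("fret stage failed: %s", exc)
    else:
        report.skipped.append("fret: no emission/absorption files configured")

    # --- thermodynamics (from fitted Ka values) -------------------------
    if len(ka_by_T) >= 2:
        try:
            result = thermo.vant_hoff_analysis(ka_by_T)
            report.thermo = _asdict_enumsafe(result)
        except SpecbindError as exc:
            report.errors.append(f"thermo: {exc}")
    else:
        report.skipped.append("thermo: needs fitted Ka at >= 2 temperatures")

    # --- ligand efficiency ---------------------------------------------
    for entry in cfg.get("ligands", []):
        try:
            record = thermo.LigandRecord(
                name=entry["name"],
                formula=entry["formula"],
                binding_energy_kcal=float(entry["binding_energy_kcal"]),
            )
            report.ligands.append(_asdict_enumsafe(record))
        except (SpecbindError, KeyError) as exc:
            report.errors.append(f"ligand {entry.get('name', '?')}: {exc}")

    # --- FTIR -----------------------------------------------------------
    icfg = cfg.get("ftir")
    if icfg:
        try:
            p = _require_file(icfg["spectrum"], "ftir")
            digests[str(p)] = _digest(p)
            spectrum = read_spectrum(p, AxisKind.WAVENUMBER_CM1, SignalKind.FTIR_ABSORBANCE)
            bands, composition = ftir.analyze_amide_i(spectrum)
            report.secondary_structure = {
                "percent": composition.as_dict(),
                "bands": [_asdict_enumsafe(b) | {"area": float(b.area)} for b in bands],
            }
        except SpecbindError as exc:
            report.errors.append(f"ftir: {exc}")
            logger.error("ftir stage failed: %s", exc)
    else:
        report.skipped.append("ftir: no spectrum configured")

    # --- EEM ------------------------------------------------------------
    ecfg = cfg.get("eem")
    if ecfg:
        try:
            ref_path = _require_file(ecfg["reference"], "eem")
            trt_path = _require_file(ecfg["treated"], "eem")
            digests[str(ref_path)] = _digest(ref_path)
            digests[str(trt_path)] = _digest(trt_path)
            shifts = eem.compare_eems(
                read_eem(ref_path),
                read_eem(trt_path),
                scatter_half_width_nm=float(
                    ecfg.get("scatter_half_width_nm", eem.DEFAULT_SCATTER_HALF_WIDTH_NM)
                ),
            )
            report.eem_shifts = [_asdict_enumsafe(s) for s in shifts]
        except SpecbindError as exc:
            report.errors.append(f"eem: {exc}")
            logger.error("eem stage failed: %s", exc)
    else:
        report.skipped.append("eem: no reference/treated EEMs configured")

    report.provenance = {
        "version": __version__,
        "seed": cfg.get("seed"),
        "config": {k: v for k, v in cfg.items()},
        "input_sha256": digests,
    }
    return report
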