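"""CSV and configuration I/O.

Trace CSVs carry nine columns (``time_ms, vcmd_mV, vm_mV, vp_mV,
vclamp_mV, vest_mV, iion_nA, iout_nA, ipost_nA``) in full precision with a
'.' decimal separator; optional ``#``-prefixed header comment lines carry
provenance (seed, config hash).  I-V CSVs carry ``voltage_mV,
peak_current_nA, time_to_peak_ms`` plus ``sem`` for aggregates.

Configuration is a single YAML document with nested sections ``amplifier``,
``cell``, ``ionic_model``, ``protocol`` and ``solver`` (plus an optional
top-level ``seed``); field names match the dataclass fields exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .amplifier import AmplifierSettings, CellProperties
from .experiments import IVCurve
from .ionic import GenericINa, GenericINaParams, IonicModel, ModelCell, ModelCellParams
from .protocols import Protocol, build_iv_protocol, build_step_protocol
from .simulate import SolverOptions, Trace

__all__ = [
    "TRACE_COLUMNS",
    "trace_to_csv",
    "trace_from_csv",
    "iv_to_csv",
    "iv_from_csv",
    "RunConfig",
    "load_config",
    "config_hash",
]

TRACE_COLUMNS = [
    "time_ms", "vcmd_mV", "vm_mV", "vp_mV", "vclamp_mV", "vest_mV",
    "iion_nA", "iout_nA", "ipost_nA",
]

_FMT = "%.17g"  # round-trips doubles exactly


def _write_with_comments(df: pd.DataFrame, path, comments: list[str]) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format=_FMT)


def trace_to_csv(trace: Trace, path, comments: list[str] | None = None) -> None:
    df = pd.DataFrame(
        {
            "time_ms": trace.t,
            "vcmd_mV": trace.Vcmd,
            "vm_mV": trace.Vm,
            "vp_mV": trace.Vp,
            "vclamp_mV": trace.Vclamp,
            "vest_mV": trace.Vest,
            "iion_nA": trace.Iion,
            "iout_nA": trace.Iout,
            "ipost_nA": trace.Ipost,
        }
    )
    _write_with_comments(df, path, comments or [])


def trace_from_csv(path) -> Trace:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV {path} missing columns: {sorted(missing)}")
    return Trace(
        t=df["time_ms"].to_numpy(),
        Vcmd=df["vcmd_mV"].to_numpy(),
        Vm=df["vm_mV"].to_numpy(),
        Vp=df["vp_mV"].to_numpy(),
        Vclamp=df["vclamp_mV"].to_numpy(),
        Vest=df["vest_mV"].to_numpy(),
        Iion=df["iion_nA"].to_numpy(),
        Iout=df["iout_nA"].to_numpy(),
        Ipost=df["ipost_nA"].to_numpy(),
    )


def iv_to_csv(curve: IVCurve, path, comments: list[str] | None = None) -> None:
    data = {
        "voltage_mV": curve.voltages,
        "peak_current_nA": curve.peak_currents,
        "time_to_peak_ms": curve.time_to_peak,
    }
    if curve.sem is not None:
        data["sem"] = curve.sem
    _write_with_comments(pd.DataFrame(data), path, comments or [])


def iv_from_csv(path) -> IVCurve:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return IVCurve(
        voltages=df["voltage_mV"].to_numpy(),
        peak_currents=df["peak_current_nA"].to_numpy(),
        time_to_peak=df["time_to_peak_ms"].to_numpy(),
        sem=df["sem"].to_numpy() if "sem" in df.columns else None,
    )


@dataclass
class RunConfig:
    """Validated run configuration assembled from a YAML document."""

    amplifier: AmplifierSettings
    cell: CellProperties
    model: IonicModel
    protocols: list[Protocol]
    solver: SolverOptions
    seed: int = 0
    raw: dict = field(default_factory=dict)


def _build_model(section: dict) -> IonicModel:
    section = dict(section)
    kind = section.pop("type", None)
    if kind == "model_cell":
        return ModelCell(ModelCellParams(**section))
    if kind == "generic_ina":
        return GenericINa(GenericINaParams(**section))
    raise ValueError(
        f"ionic_model.type must be 'model_cell' or 'generic_ina', got {kind!r}"
    )


def _build_protocols(section) -> list[Protocol]:
    if isinstance(section, list):  # raw [[level_mV, duration_ms], ...]
        return [Protocol(tuple((float(v), float(d)) for v, d in section))]
    section = dict(section)
    kind = section.pop("type", "segments")
    if kind == "step":
        return [build_step_protocol(**section)]
    if kind == "iv":
        return build_iv_protocol(**section)
    if kind == "segments":
        return [
            Protocol(tuple((float(v), float(d)) for v, d in section["segments"]))
        ]
    raise ValueError(f"unknown protocol type {kind!r}")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Validation errors name the offending section and field (the dataclass
    constructors raise with the field name).
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"config {path} must be a mapping")
    try:
        amplifier = AmplifierSettings(**doc.get("amplifier", {}))
    except (TypeError, ValueError) as exc:
        raise ValueError(f"config section 'amplifier': {exc}") from exc
    try:
        cell = CellProperties(**doc.get("cell", {}))
    except (TypeError, ValueError) as exc:
        raise ValueError(f"config section 'cell': {exc}") from exc
    try:
        model = _build_model(doc.get("ionic_model", {"type": "model_cell"}))
    except (TypeError, ValueError) as exc:
        raise ValueError(f"config section 'ionic_model': {exc}") from exc
    try:
        protocols = _build_protocols(doc.get("protocol", {"type": "segments", "segments": [[-80.0, 20.0]]}))
    except (TypeError, ValueError, KeyError) as exc:
        raise ValueError(f"config section 'protocol': {exc}") from exc
    try:
        solver = SolverOptions(**doc.get("solver", {}))
    except (TypeError, ValueError) as exc:
        raise ValueError(f"config section 'solver': {exc}") from exc
    return RunConfig(
        amplifier=amplifier,
        cell=cell,
        model=model,
        protocols=protocols,
        solver=solver,
        seed=int(doc.get("seed", 0)),
        raw=doc,
    )


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the raw configuration document."""
    blob = json.dumps(config.raw, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
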