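"""Delimited-text and JSON plumbing shared by the CLI and pipeline.

Curves travel as comma-separated text with one header line
(``prepulse_mV,current_norm`` or ``conc_nM,inhibition``), trajectories as
tidy long-format tables (``time_ms,state,occupancy``), and fit results as
JSON records carrying parameters, uncertainties and the convergence flag.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inference import (
    AvailabilityCurve,
    BoltzmannFitResult,
    DoseResponseCurve,
    HillFitResult,
    ShiftAnalysis,
)
from .kinetics import VoltageProtocol

__all__ = [
    "read_availability",
    "write_availability",
    "read_dose_response",
    "write_dose_response",
    "boltzmann_result_record",
    "hill_result_record",
    "shift_analysis_record",
    "write_json",
    "load_config",
    "protocol_from_config",
]


def write_availability(curve: AvailabilityCurve, path) -> None:
    pd.DataFrame(
        {"prepulse_mV": curve.prepulse_v, "current_norm": curve.current_norm}
    ).to_csv(path, index=False)


def read_availability(path, drug_conc: float = 0.0, **kw) -> AvailabilityCurve:
    df = pd.read_csv(path)
    for col in ("prepulse_mV", "current_norm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return AvailabilityCurve(
        df["prepulse_mV"].to_numpy(), df["current_norm"].to_numpy(),
        drug_conc=drug_conc, **kw,
    )


def write_dose_response(curve: DoseResponseCurve, path) -> None:
    pd.DataFrame({"conc_nM": curve.conc, "inhibition": curve.inhibition}).to_csv(
        path, index=False
    )


def read_dose_response(path, **kw) -> DoseResponseCurve:
    df = pd.read_csv(path)
    for col in ("conc_nM", "inhibition"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return DoseResponseCurve(df["conc_nM"].to_numpy(), df["inhibition"].to_numpy(), **kw)


def boltzmann_result_record(fit: BoltzmannFitResult) -> dict:
    return {
        "v_half_mV": fit.params.v_half,
        "slope_mV": fit.params.slope,
        "amplitude": fit.params.amplitude,
        "rss": fit.rss,
        "converged": fit.converged,
        "stderr": fit.stderr,
    }


def hill_result_record(fit: HillFitResult) -> dict:
    return {
        "ic50_nM": fit.ic50,
        "hill_n": fit.hill_n,
        "rss": fit.rss,
        "converged": fit.converged,
        "stderr": fit.stderr,
    }


def shift_analysis_record(a: ShiftAnalysis) -> dict:
    return {
        "control_fit": boltzmann_result_record(a.control_fit),
        "drug_fit": boltzmann_result_record(a.drug_fit),
        "raw_shift_mV": a.raw_shift,
        "control_drift_mV": a.control_drift,
        "corrected_shift_mV": a.corrected_shift,
        "kd_rest_nM": None if np.isinf(a.kd_rest) else a.kd_rest,
        "kd_inact_nM": None if np.isinf(a.kd_inact) else a.kd_inact,
    }


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_config(path) -> dict:
    """Load a YAML/JSON config file into a dict."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def protocol_from_config(cfg: dict) -> VoltageProtocol:
    """Build a VoltageProtocol from a config block.

    Expected keys: ``epochs`` (list of [voltage_mV, duration_ms]),
    ``measure_epochs`` (list of epoch indices), optional ``label``.
    """
    allowed = {"epochs", "measure_epochs", "label"}
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"unknown protocol keys: {sorted(unknown)}")
    epochs = tuple((float(v), float(d)) for v, d in cfg["epochs"])
    return VoltageProtocol(
        epochs=epochs,
        measure_epochs=tuple(int(i) for i in cfg.get("measure_epochs", ())),
        label=str(cfg.get("label", "")),
    )
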