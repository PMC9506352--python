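"""File formats: PlateCSV + JSON sidecar, calibrated traces, metrics,
temperature logs, fit/dose JSON.

The plate format is deliberately simple and auditable: a long CSV with
columns ``well_id,time_s,counts`` plus a JSON sidecar holding the run-level
protocol (sampling interval, integration window, stimulus and discharge
times) and optional per-well annotations (treatment, dilution).  No
instrument-vendor formats are parsed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalciumTrace, LuminescenceTrace
from .signatures import SignatureMetrics
from .thermal import EnergyDose, TemperatureSeries, ThermalFit

__all__ = [
    "write_plate",
    "read_plate",
    "write_calcium",
    "read_calcium",
    "write_metrics",
    "read_metrics",
    "write_temperature",
    "read_temperature",
    "write_json",
    "read_json",
    "fit_to_dict",
    "dose_to_dict",
]


def write_plate(traces: list[LuminescenceTrace], csv_path, meta_path) -> None:
    """Write traces to PlateCSV (well_id,time_s,counts) + metadata sidecar."""
    frames = [
        pd.DataFrame(
            {"well_id": t.well_id, "time_s": t.times, "counts": t.counts.astype(int)}
        )
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    first = traces[0]
    intervals = np.diff(first.times)
    meta = {
        "sampling_interval_s": float(intervals[0]) if intervals.size else None,
        "integration_window_s": first.integration_window,
        "stimulus_time_s": first.stimulus_time,
        "discharge_time_s": first.discharge_time,
        "wells": {t.well_id: dict(t.metadata) for t in traces},
    }
    Path(meta_path).write_text(json.dumps(meta, indent=2))


def read_plate(csv_path, meta_path) -> list[LuminescenceTrace]:
    """Parse PlateCSV + sidecar into validated traces.

    Raises on a missing discharge time (calibration would be impossible),
    duplicated (well, time) rows, or non-monotone times, naming the well.
    """
    df = pd.read_csv(csv_path)
    required = {"well_id", "time_s", "counts"}
    if not required.issubset(df.columns):
        raise ValueError(f"plate CSV must have columns {sorted(required)}")
    meta = json.loads(Path(meta_path).read_text())
    discharge = meta.get("discharge_time_s")
    if discharge is None:
        raise ValueError("metadata missing discharge_time_s: calibration impossible")
    if df.duplicated(subset=["well_id", "time_s"]).any():
        bad = df[df.duplicated(subset=["well_id", "time_s"])]["well_id"].iloc[0]
        raise ValueError(f"duplicated (well, time) rows (well {bad})")
    wells_meta = meta.get("wells", {})
    traces = []
    for well_id, grp in df.groupby("well_id", sort=False):
        times = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"non-monotone times in well {well_id}")
        traces.append(
            LuminescenceTrace(
                well_id=str(well_id),
                times=times,
                counts=grp["counts"].to_numpy(dtype=float),
                integration_window=float(meta["integration_window_s"]),
                stimulus_time=float(meta["stimulus_time_s"]),
                discharge_time=float(discharge),
                metadata=dict(wells_meta.get(str(well_id), {})),
            )
        )
    return traces


def write_calcium(traces: list[CalciumTrace], csv_path, provenance_path=None) -> None:
    """Calibrated traces as CSV (well_id,time_s,ca_molar), full precision."""
    frames = [
        pd.DataFrame({"well_id": t.well_id, "time_s": t.times, "ca_molar": t.ca})
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    if provenance_path is not None:
        prov = {
            t.well_id: {
                "calibration": None if t.provenance is None else t.provenance.__dict__,
                "flags": sorted(t.flags),
                "metadata": t.metadata,
            }
            for t in traces
        }
        Path(provenance_path).write_text(json.dumps(prov, indent=2, default=str))


def read_calcium(csv_path, provenance_path=None) -> list[CalciumTrace]:
    df = pd.read_csv(csv_path)
    prov = (
        json.loads(Path(provenance_path).read_text())
        if provenance_path is not None
        else {}
    )
    traces = []
    for well_id, grp in df.groupby("well_id", sort=False):
        entry = prov.get(str(well_id), {})
        traces.append(
            CalciumTrace(
                well_id=str(well_id),
                times=grp["time_s"].to_numpy(dtype=float),
                ca=grp["ca_molar"].to_numpy(dtype=float),
                flags=set(entry.get("flags", [])),
                metadata=entry.get("metadata", {}),
            )
        )
    return traces


def metrics_frame(records: list[tuple[str, SignatureMetrics]]) -> pd.DataFrame:
    """Rows of (well_id, metrics) -> tidy table, one row per well per epoch."""
    rows = []
    for well_id, m in records:
        row = {"well_id": well_id}
        row.update(m.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def write_metrics(df: pd.DataFrame, csv_path, json_path=None) -> None:
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(df.to_json(orient="records", indent=2))


def read_metrics(csv_path) -> pd.DataFrame:
    return pd.read_csv(csv_path)


def write_temperature(series: TemperatureSeries, csv_path) -> None:
    pd.DataFrame(
        {"time_s": series.times, "temp_C": series.temps, "phase": series.phase}
    ).to_csv(csv_path, index=False)


def read_temperature(csv_path, activation_time: float | None = None) -> TemperatureSeries:
    df = pd.read_csv(csv_path)
    phase = df["phase"].to_numpy() if "phase" in df.columns else None
    if activation_time is None:
        if phase is None:
            raise ValueError("need either a phase column or an activation_time")
        heating = df["time_s"][df["phase"] == "heating"]
        activation_time = float(heating.max())
    return TemperatureSeries(
        times=df["time_s"].to_numpy(dtype=float),
        temps=df["temp_C"].to_numpy(dtype=float),
        activation_time=activation_time,
        phase=phase,
    )


def fit_to_dict(fit: ThermalFit) -> dict:
    return {
        "Pin_hat_W": fit.Pin_hat,
        "Rcond_hat_W_per_K": fit.Rcond_hat,
        "A_hat": fit.A_hat,
        "B_hat": fit.B_hat,
        "T0_hat_C": fit.T0_hat,
        "residual_rms_heating_K": fit.residual_rms_heating,
        "residual_rms_decay_K": fit.residual_rms_decay,
        "flags": sorted(fit.flags),
    }


def dose_to_dict(dose: EnergyDose) -> dict:
    return {
        "energy_per_mass_J_per_kg": dose.energy_per_mass,
        "effective_power_W": dose.effective_power,
        "activation_time_s": dose.activation_time,
    }


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float))


def read_json(path):
    return json.loads(Path(path).read_text())
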