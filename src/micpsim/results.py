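"""Result collection and CSV serialization.

A :class:`ResultSet` holds time-stamped axial profiles (snapshots),
breakthrough series at the outflow face, a cumulative mass ledger and
the fully resolved scenario, which suffices to reproduce the run
exactly.  In-memory frames use SI units (solutes in mol/m^3); written
CSV files mirror the bench conventions (solutes in mol/L).
"""

from __future__ import annotations

import glob
import os
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from . import units
from .hydraulics import state_density
from .state import ColumnState

SNAPSHOT_COLUMNS = ["x_m", "phi", "k_ms", "C_urea", "C_Ca", "C_NH4",
                    "C_bacl", "C_bacs", "C_CaCO3", "rho_l"]
_MOLAR_COLUMNS = ("C_urea", "C_Ca", "C_NH4")
_SPECIES_COLUMN = {"urea": "C_urea", "ca": "C_Ca", "nh4": "C_NH4",
                   "bacl": "C_bacl", "bacs": "C_bacs", "caco3": "C_CaCO3"}
_FLOAT_FMT = "%.12g"


@dataclass
class Snapshot:
    time: float
    phase_index: int
    label: str
    frame: pd.DataFrame


@dataclass
class ResultSet:
    """Snapshots, breakthrough, mass ledger and reproduction metadata."""

    scenario: object
    snapshots: List[Snapshot]
    series: pd.DataFrame
    breakthrough: pd.DataFrame
    metadata: dict
    final_state: Optional[ColumnState] = None

    def phase_end(self, kind: str) -> Snapshot:
        """Last snapshot taken at the end of a phase of the given kind."""
        label = f"{kind}_end"
        for snap in reversed(self.snapshots):
            if snap.label == label:
                return snap
        raise KeyError(f"no phase-end snapshot labelled {label!r}")

    def species_column(self, species: str) -> str:
        return _SPECIES_COLUMN[species]


def state_frame(state: ColumnState, fluid) -> pd.DataFrame:
    return pd.DataFrame({
        "x_m": state.x,
        "phi": state.phi,
        "k_ms": state.k_cond,
        "C_urea": state.c_urea,
        "C_Ca": state.c_ca,
        "C_NH4": state.c_nh4,
        "C_bacl": state.c_bacl,
        "C_bacs": state.c_bacs,
        "C_CaCO3": state.c_caco3,
        "rho_l": state_density(state, fluid),
    })


class Recorder:
    """Accumulates snapshots, breakthrough rows and the mass ledger."""

    def __init__(self, scenario):
        self.scenario = scenario
        self.snapshots: List[Snapshot] = []
        self._bt_rows: list = []
        self._series_rows: list = []
        self.cum_urea_converted = 0.0
        self.cum_in = {sp: 0.0 for sp in ("urea", "ca", "nh4", "bacl")}
        self.cum_out = {sp: 0.0 for sp in ("urea", "ca", "nh4", "bacl")}
        self.n_steps = 0
        self.min_dt = np.inf

    def accumulate(self, report, state: ColumnState, moles_converted: float):
        self.cum_urea_converted += moles_converted
        for sp in self.cum_in:
            self.cum_in[sp] += report.influx.get(sp, 0.0)
            self.cum_out[sp] += report.outflux.get(sp, 0.0)
        self.n_steps += 1
        self.min_dt = min(self.min_dt, report.dt)

    def snapshot(self, state: ColumnState, scn, bc, phase_idx: int, label: str):
        self.snapshots.append(Snapshot(
            time=state.time,
            phase_index=phase_idx,
            label=label,
            frame=state_frame(state, scn.fluid),
        ))
        row = {"time_s": state.time, "phase": phase_idx,
               "cum_urea_converted_mol": self.cum_urea_converted,
               "cum_nh4_produced_mol": 2.0 * self.cum_urea_converted,
               "caco3_kg": state.total_caco3_mass()}
        for sp in self.cum_in:
            row[f"cum_in_{sp}"] = self.cum_in[sp]
            row[f"cum_out_{sp}"] = self.cum_out[sp]
        self._series_rows.append(row)
        if bc is not None and bc.rate > 0.0:
            out_cell = 0 if bc.source_end == "top" else -1
            self._bt_rows.append({
                "time_s": state.time,
                "phase": phase_idx,
                "outflow_end": "bottom" if bc.source_end == "top" else "top",
                "C_urea": state.c_urea[out_cell],
                "C_Ca": state.c_ca[out_cell],
                "C_NH4": state.c_nh4[out_cell],
                "C_bacl": state.c_bacl[out_cell],
            })

    def finalize(self, state: ColumnState) -> ResultSet:
        from . import __version__
        from .config import scenario_to_dict

        bt_cols = ["time_s", "phase", "outflow_end",
                   "C_urea", "C_Ca", "C_NH4", "C_bacl"]
        breakthrough = pd.DataFrame(self._bt_rows, columns=bt_cols)
        series = pd.DataFrame(self._series_rows)
        metadata = {
            "scenario": scenario_to_dict(self.scenario),
            "code_version": __version__,
            "numerics_report": {
                "n_steps": self.n_steps,
                "min_dt_s": None if np.isinf(self.min_dt) else float(self.min_dt),
                "n_cells": int(state.n_cells),
                "clogged_cells": int(np.sum(state.clogged)),
            },
        }
        return ResultSet(
            scenario=self.scenario,
            snapshots=self.snapshots,
            series=series,
            breakthrough=breakthrough,
            metadata=metadata,
            final_state=state,
        )


def _to_output_units(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    for col in _MOLAR_COLUMNS:
        out[col] = out[col].map(units.mol_per_m3_to_mol_per_l)
    return out


def _to_si_units(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    for col in _MOLAR_COLUMNS:
        out[col] = out[col].map(units.mol_per_l_to_mol_per_m3)
    return out


def write_results(result: ResultSet, outdir: str) -> List[str]:
    """Write profile/breakthrough/series/metrics CSVs and the resolved config.

    File naming is deterministic; a re-run from the written resolved
    configuration reproduces the files byte-identically.
    """
    import yaml

    from .metrics import metrics_table

    os.makedirs(outdir, exist_ok=True)
    written = []
    for i, snap in enumerate(result.snapshots):
        name = f"profile_{i:04d}_{snap.label}.csv"
        path = os.path.join(outdir, name)
        frame = _to_output_units(snap.frame).assign(
            time_s=snap.time, phase=snap.phase_index)
        frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
        written.append(path)

    bt_path = os.path.join(outdir, "breakthrough.csv")
    bt = result.breakthrough.copy()
    for col in _MOLAR_COLUMNS:
        if col in bt.columns and len(bt):
            bt[col] = bt[col].map(units.mol_per_m3_to_mol_per_l)
    bt.to_csv(bt_path, index=False, float_format=_FLOAT_FMT)
    written.append(bt_path)

    series_path = os.path.join(outdir, "series.csv")
    result.series.to_csv(series_path, index=False, float_format=_FLOAT_FMT)
    written.append(series_path)

    metrics_path = os.path.join(outdir, "metrics.csv")
    metrics_table(result).to_csv(metrics_path, index=False, float_format=_FLOAT_FMT)
    written.append(metrics_path)

    cfg_path = os.path.join(outdir, "scenario.yaml")
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(result.metadata["scenario"], fh, sort_keys=False)
    written.append(cfg_path)
    return written


def read_results(outdir: str) -> ResultSet:
    """Reload a result directory written by :func:`write_results`."""
    from .config import load_scenario

    scenario = load_scenario(os.path.join(outdir, "scenario.yaml"))
    snapshots = []
    for path in sorted(glob.glob(os.path.join(outdir, "profile_*.csv"))):
        raw = pd.read_csv(path)
        label = os.path.basename(path)[:-4].split("_", 2)[2]
        time = float(raw["time_s"].iloc[0])
        phase = int(raw["phase"].iloc[0])
        frame = _to_si_units(raw[SNAPSHOT_COLUMNS])
        snapshots.append(Snapshot(time=time, phase_index=phase,
                                  label=label, frame=frame))
    series = pd.read_csv(os.path.join(outdir, "series.csv"))
    breakthrough = pd.read_csv(os.path.join(outdir, "breakthrough.csv"))
    if len(breakthrough):
        for col in _MOLAR_COLUMNS:
            breakthrough[col] = breakthrough[col].map(units.mol_per_l_to_mol_per_m3)
    return ResultSet(scenario=scenario, snapshots=snapshots, series=series,
                     breakthrough=breakthrough,
                     metadata={"scenario": None}, final_state=None)
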