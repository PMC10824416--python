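"""Scenario loading, validation and round-trip serialization.

Authored configuration files (YAML or JSON) may use bench units
(mL/min, mol/L, cm/s, hours) or SI; resolved scenarios are written back
in SI so that a reload reproduces the scenario exactly.  Validation
errors name the offending field path.
"""

from __future__ import annotations

from typing import Any, Mapping

import yaml

from . import units
from .dispersivity import ScalingLaw
from .errors import ConfigurationError
from .hydraulics import FluidProps
from .kinetics import KineticParams
from .porosity_permeability import MediumParams
from .scheduler import DispersionSpec, Geometry, Numerics, PhaseSpec, Scenario

_SECTIONS = ("name", "geometry", "medium", "fluid", "kinetics",
             "dispersion", "numerics", "phases")


def _require(mapping: Mapping, key: str, path: str):
    if key not in mapping:
        raise ConfigurationError(f"missing required field {path}.{key}")
    return mapping[key]


def _pick(mapping: Mapping, path: str, *candidates, default=None, required=False,
          convert=None):
    """First present key among unit-suffixed aliases, with conversion."""
    for key, factor in candidates:
        if key in mapping:
            value = mapping[key]
            if value is None:
                continue
            value = float(value)
            value = factor(value) if callable(factor) else value * factor
            return convert(value) if convert else value
    if required:
        names = ", ".join(k for k, _ in candidates)
        raise ConfigurationError(f"missing required field {path} (one of: {names})")
    return default


def _check_known(mapping: Mapping, allowed, path: str):
    unknown = set(mapping) - set(allowed)
    if unknown:
        raise ConfigurationError(
            f"unknown field(s) {sorted(unknown)} in {path}; allowed: {sorted(allowed)}")


def _phase_from_dict(d: Mapping, idx: int) -> PhaseSpec:
    path = f"phases[{idx}]"
    kind = _require(d, "kind", path)
    allowed = {"kind", "flow_type", "duration_s", "duration_h", "rate_m3_s",
               "rate_mL_min", "volume_mL", "volume_m3", "source", "injected",
               "cells_per_mL", "urea_mol_L", "nh4_mol_L", "ca_mol_L",
               "pulse_period_s", "pulse_period_h", "pulse_volume_m3",
               "pulse_volume_mL", "n_pulses"}
    _check_known(d, allowed, path)
    rate = _pick(d, f"{path}.rate", ("rate_m3_s", 1.0),
                 ("rate_mL_min", units.ml_per_min_to_m3_per_s), default=0.0)
    duration = _pick(d, f"{path}.duration", ("duration_s", 1.0),
                     ("duration_h", units.hours_to_s))
    volume = _pick(d, f"{path}.volume", ("volume_m3", 1.0), ("volume_mL", units.ML))
    if duration is None and volume is not None:
        if rate <= 0.0:
            raise ConfigurationError(f"{path}: volume given but rate is zero")
        duration = volume / rate
    n_pulses = d.get("n_pulses")
    pulse_period = _pick(d, f"{path}.pulse_period", ("pulse_period_s", 1.0),
                         ("pulse_period_h", units.hours_to_s))
    if duration is None and pulse_period is not None and n_pulses is not None:
        duration = pulse_period * int(n_pulses)
    if duration is None:
        raise ConfigurationError(
            f"{path}: needs duration_s/duration_h (or volume+rate, or pulses)")

    injected: dict[str, float] = {}
    if "injected" in d and d["injected"] is not None:
        injected.update({k: float(v) for k, v in d["injected"].items()})
    if "cells_per_mL" in d and d["cells_per_mL"] is not None:
        injected["bacl"] = float(d["cells_per_mL"])
    for key, species in (("urea_mol_L", "urea"), ("nh4_mol_L", "nh4"),
                         ("ca_mol_L", "ca")):
        if key in d and d[key] is not None:
            injected[species] = units.mol_per_l_to_mol_per_m3(float(d[key]))

    flow_type = d.get("flow_type", "none" if kind == "R" else "continuous")
    return PhaseSpec(
        kind=kind,
        duration=float(duration),
        flow_type=flow_type,
        rate=float(rate),
        source_end=d.get("source"),
        injected=injected,
        pulse_period=pulse_period,
        pulse_volume=_pick(d, f"{path}.pulse_volume", ("pulse_volume_m3", 1.0),
                           ("pulse_volume_mL", units.ML)),
    )


def dict_to_scenario(doc: Mapping[str, Any]) -> Scenario:
    if not isinstance(doc, Mapping):
        raise ConfigurationError("scenario document must be a mapping")
    _check_known(doc, _SECTIONS, "scenario")

    geo_d = _require(doc, "geometry", "scenario")
    _check_known(geo_d, {"length_m", "area_m2", "n_cells"}, "geometry")
    geometry = Geometry(
        length=_pick(geo_d, "geometry.length_m", ("length_m", 1.0), required=True),
        **({"area": float(geo_d["area_m2"])} if geo_d.get("area_m2") is not None else {}),
        n_cells=int(geo_d["n_cells"]) if geo_d.get("n_cells") is not None else None,
    )

    med_d = doc.get("medium", {}) or {}
    _check_known(med_d, {"phi0", "k0_m_s", "k0_cm_s", "phi_c", "a", "kc_form"},
                 "medium")
    med_kwargs = {}
    if "phi0" in med_d:
        med_kwargs["phi_0"] = float(med_d["phi0"])
    k0 = _pick(med_d, "medium.k0", ("k0_m_s", 1.0),
               ("k0_cm_s", units.cm_per_s_to_m_per_s))
    if k0 is not None:
        med_kwargs["k_0"] = k0
    for src, dst in (("phi_c", "phi_c"), ("a", "a"), ("kc_form", "kc_form")):
        if src in med_d:
            med_kwargs[dst] = med_d[src]
    try:
        medium = MediumParams(**med_kwargs)
    except Exception as exc:
        raise ConfigurationError(f"medium: {exc}") from exc

    fl_d = doc.get("fluid", {}) or {}
    fluid_fields = {"rho_w", "mu_l", "d_mol", "m_urea", "m_ca", "m_nh4",
                    "m_caco3", "rho_c", "g"}
    _check_known(fl_d, fluid_fields, "fluid")
    fluid = FluidProps(**{k: float(v) for k, v in fl_d.items()})

    kin_d = doc.get("kinetics", {}) or {}
    _check_known(kin_d, {"u_sp", "k_m", "t_d", "k_d", "k_att"}, "kinetics")
    kinetics = KineticParams(**{k: float(v) for k, v in kin_d.items()})

    disp_d = doc.get("dispersion", {}) or {}
    _check_known(disp_d, {"mode", "alpha_L_m", "transverse_ratio", "law"},
                 "dispersion")
    law = ScalingLaw()
    if disp_d.get("law") is not None:
        law_d = disp_d["law"]
        _check_known(law_d, {"slope", "intercept", "r_squared"}, "dispersion.law")
        law = ScalingLaw(
            slope=float(law_d.get("slope", law.slope)),
            intercept=float(law_d.get("intercept", law.intercept)),
            r_squared=(float(law_d["r_squared"])
                       if law_d.get("r_squared") is not None else None),
        )
    dispersion = DispersionSpec(
        mode=disp_d.get("mode", "scale_effect"),
        alpha_l=(float(disp_d["alpha_L_m"])
                 if disp_d.get("alpha_L_m") is not None else None),
        transverse_ratio=float(disp_d.get("transverse_ratio", 10.0)),
        law=law,
    )

    num_d = doc.get("numerics", {}) or {}
    _check_known(num_d, {"cfl", "dif_number", "snapshots_per_phase",
                         "urease_clock"}, "numerics")
    numerics = Numerics(
        cfl=float(num_d.get("cfl", 0.9)),
        dif_number=float(num_d.get("dif_number", 0.4)),
        snapshots_per_phase=int(num_d.get("snapshots_per_phase", 20)),
        urease_clock=num_d.get("urease_clock", "end_of_phase_B"),
    )

    phases = tuple(_phase_from_dict(p, i)
                   for i, p in enumerate(doc.get("phases", []) or []))
    return Scenario(
        geometry=geometry, medium=medium, fluid=fluid, kinetics=kinetics,
        dispersion=dispersion, phases=phases, numerics=numerics,
        name=str(doc.get("name", "scenario")),
    )


def scenario_to_dict(scn: Scenario) -> dict:
    """Resolved scenario as a plain SI-unit document (exact round-trip)."""
    scn = scn.resolve()
    phases = []
    for p in scn.phases:
        entry: dict[str, Any] = {"kind": p.kind, "duration_s": p.duration,
                                 "flow_type": p.flow_type}
        if p.rate:
            entry["rate_m3_s"] = p.rate
        if p.source_end:
            entry["source"] = p.source_end
        if p.injected:
            entry["injected"] = {k: float(v) for k, v in sorted(p.injected.items())}
        if p.pulse_period is not None:
            entry["pulse_period_s"] = p.pulse_period
        if p.pulse_volume is not None:
            entry["pulse_volume_m3"] = p.pulse_volume
        phases.append(entry)
    law = scn.dispersion.law
    return {
        "name": scn.name,
        "geometry": {"length_m": scn.geometry.length,
                     "area_m2": scn.geometry.area,
                     "n_cells": scn.geometry.n_cells},
        "medium": {"phi0": scn.medium.phi_0, "k0_m_s": scn.medium.k_0,
                   "phi_c": scn.medium.phi_c, "a": scn.medium.a,
                   "kc_form": scn.medium.kc_form},
        "fluid": {"rho_w": scn.fluid.rho_w, "mu_l": scn.fluid.mu_l,
                  "d_mol": scn.fluid.d_mol, "m_urea": scn.fluid.m_urea,
                  "m_ca": scn.fluid.m_ca, "m_nh4": scn.fluid.m_nh4,
                  "m_caco3": scn.fluid.m_caco3, "rho_c": scn.fluid.rho_c,
                  "g": scn.fluid.g},
        "kinetics": {"u_sp": scn.kinetics.u_sp, "k_m": scn.kinetics.k_m,
                     "t_d": scn.kinetics.t_d, "k_d": scn.kinetics.k_d,
                     "k_att": scn.kinetics.k_att},
        "dispersion": {"mode": scn.dispersion.mode,
                       "alpha_L_m": scn.dispersion.alpha_l,
                       "transverse_ratio": scn.dispersion.transverse_ratio,
                       "law": {"slope": law.slope, "intercept": law.intercept,
                               "r_squared": law.r_squared}},
        "numerics": {"cfl": scn.numerics.cfl,
                     "dif_number": scn.numerics.dif_number,
                     "snapshots_per_phase": scn.numerics.snapshots_per_phase,
                     "urease_clock": scn.numerics.urease_clock},
        "phases": phases,
    }


def load_scenario(path) -> Scenario:
    """Load and validate a YAML/JSON scenario file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    scn = dict_to_scenario(doc)
    # cross-field physical consistency beyond per-section checks
    if scn.medium.phi_c >= scn.medium.phi_0:
        raise ConfigurationError(
            f"medium.phi_c ({scn.medium.phi_c}) must be below medium.phi0 "
            f"({scn.medium.phi_0})")
    return scn


def save_scenario(scn: Scenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(scn), fh, sort_keys=False)
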