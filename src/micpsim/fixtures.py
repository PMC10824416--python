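"""Built-in scenarios: the calibration/verification columns and the
parametric case matrix.

Three bench columns (0.5 m sand columns) calibrate and verify the
model:

* ``test1B`` (calibration): phi0 = 0.37, k0 = 3e-2 cm/s; 442.1 mL of
  7.2e5 cells/mL bacterial suspension at 10 mL/min from the top; 8.3 h
  retention; 81.267 h of 0.3:0.3:0.1 mol/L urea:NH4:Ca cementation
  solution at 2.2 mL/min from the bottom.
* ``test2B`` (verification): phi0 = 0.35, k0 = 3.5e-3 cm/s; 393.9 mL of
  2.5e5 cells/mL at 10 mL/min from the bottom; 12 h retention; 48.769 h
  of 0.3:0.3:0.1 at 4.4 mL/min from the bottom.
* ``test3A`` (verification): phi0 = 0.36, k0 = 2.2e-2 cm/s; 598.4 mL of
  4.3e5 cells/mL at 10 mL/min from the top; 8 h retention; pulsed
  cementation (0.05:0.05:0.05 mol/L at 10 mL/min, one 2 h period per
  pulse) from the bottom.

The parametric matrix (``table4_standard`` and the sweeps) varies the
bacterial injection rate q1 (5/10/15/20/25 mL/min), the initial
porosity (0.35...0.43) and the scale size L0 (0.1/0.5/1/5/10 m) about a
standard group (bold: q1 = 10 mL/min, phi0 = 0.37, L0 = 0.5 m,
k0 = 3e-4 m/s, 442.1 mL of 7.2e5 cells/mL, 8.3 h retention, 0.3:0.3:0.1
mol/L at 2.2 mL/min for 81.267 h).
"""

from __future__ import annotations

from typing import Iterable, List, Tuple

from . import units
from .errors import ConfigurationError
from .porosity_permeability import MediumParams
from .scheduler import CALIBRATION_AREA, DispersionSpec, Geometry, PhaseSpec, Scenario

#: Default number of injection/reaction periods for the pulsed
#: cementation treatment of test3A (2 h per pulse).
DEFAULT_PULSE_COUNT = 8

SCALE_SIZES = (0.1, 0.5, 1.0, 5.0, 10.0)
POROSITIES = (0.35, 0.37, 0.39, 0.41, 0.43)
INJECTION_RATES = (5.0, 10.0, 15.0, 20.0, 25.0)

_CEMENTATION_03_03_01 = {
    "urea": units.mol_per_l_to_mol_per_m3(0.3),
    "nh4": units.mol_per_l_to_mol_per_m3(0.3),
    "ca": units.mol_per_l_to_mol_per_m3(0.1),
}


def _phase_b(rate_ml_min: float, volume_ml: float, cells_per_ml: float,
             source: str) -> PhaseSpec:
    rate = units.ml_per_min_to_m3_per_s(rate_ml_min)
    return PhaseSpec(kind="B", duration=volume_ml * units.ML / rate,
                     flow_type="continuous", rate=rate, source_end=source,
                     injected={"bacl": cells_per_ml})


def _phase_r(hours: float) -> PhaseSpec:
    return PhaseSpec(kind="R", duration=units.hours_to_s(hours), flow_type="none")


def _phase_c(rate_ml_min: float, hours: float, source: str,
             injected=None) -> PhaseSpec:
    return PhaseSpec(kind="C", duration=units.hours_to_s(hours),
                     flow_type="continuous",
                     rate=units.ml_per_min_to_m3_per_s(rate_ml_min),
                     source_end=source,
                     injected=dict(injected or _CEMENTATION_03_03_01))


def _test1b() -> Scenario:
    return Scenario(
        name="test1B",
        geometry=Geometry(length=0.5, area=CALIBRATION_AREA),
        medium=MediumParams(phi_0=0.37, k_0=units.cm_per_s_to_m_per_s(3e-2)),
        phases=(
            _phase_b(10.0, 442.1, 7.2e5, "top"),
            _phase_r(8.3),
            _phase_c(2.2, 81.267, "bottom"),
        ),
    )


def _test2b() -> Scenario:
    return Scenario(
        name="test2B",
        geometry=Geometry(length=0.5, area=CALIBRATION_AREA),
        medium=MediumParams(phi_0=0.35, k_0=units.cm_per_s_to_m_per_s(3.5e-3)),
        phases=(
            _phase_b(10.0, 393.9, 2.5e5, "bottom"),
            _phase_r(12.0),
            _phase_c(4.4, 48.769, "bottom"),
        ),
    )


def _test3a(n_pulses: int = DEFAULT_PULSE_COUNT) -> Scenario:
    geometry = Geometry(length=0.5, area=CALIBRATION_AREA)
    phi0 = 0.36
    pore_volume = geometry.area * geometry.length * phi0
    rate = units.ml_per_min_to_m3_per_s(10.0)
    period = units.hours_to_s(2.0)
    cement = {"urea": units.mol_per_l_to_mol_per_m3(0.05),
              "nh4": units.mol_per_l_to_mol_per_m3(0.05),
              "ca": units.mol_per_l_to_mol_per_m3(0.05)}
    return Scenario(
        name="test3A",
        geometry=geometry,
        medium=MediumParams(phi_0=phi0, k_0=units.cm_per_s_to_m_per_s(2.2e-2)),
        phases=(
            _phase_b(10.0, 598.4, 4.3e5, "top"),
            _phase_r(8.0),
            PhaseSpec(kind="C", duration=n_pulses * period, flow_type="pulsed",
                      rate=rate, source_end="bottom", injected=cement,
                      pulse_period=period, pulse_volume=pore_volume),
        ),
    )


def table4_scenario(
    scale_size: float = 0.5,
    phi0: float = 0.37,
    q1_ml_min: float = 10.0,
    mode: str = "scale_effect",
    phases: str = "BRC",
    name: str | None = None,
) -> Scenario:
    """One cell of the parametric case matrix.

    The standard group uses the bold values (L0 = 0.5 m, phi0 = 0.37,
    q1 = 10 mL/min); ``phases`` selects a prefix of the protocol (for
    example "B" to study bacterial penetration only).  The calibration
    cross-section is reused at every scale.
    """
    # Both solutions enter through the same (bottom) grouting port in the
    # case matrix: the peak carbonate then forms near that port and the
    # cementation solution meets the attached bacteria immediately,
    # matching the single-port grouting practice the matrix emulates.
    phase_map = {
        "B": _phase_b(q1_ml_min, 442.1, 7.2e5, "bottom"),
        "R": _phase_r(8.3),
        "C": _phase_c(2.2, 81.267, "bottom"),
    }
    try:
        phase_list = tuple(phase_map[ch] for ch in phases)
    except KeyError as exc:
        raise ConfigurationError(f"unknown phase letter {exc} in {phases!r}") from exc
    if name is None:
        name = f"table4_L{scale_size:g}_phi{phi0:g}_q{q1_ml_min:g}_{mode}"
    return Scenario(
        name=name,
        geometry=Geometry(length=scale_size, area=CALIBRATION_AREA),
        medium=MediumParams(phi_0=phi0, k_0=3e-4),
        dispersion=DispersionSpec(mode=mode),
        phases=phase_list,
    )


BUILTIN_NAMES = ("test1B", "test2B", "test3A", "table4_standard")


def builtin_scenario(name: str) -> Scenario:
    """Return a built-in scenario by name.

    Unknown names raise with the list of available fixtures.
    """
    factories = {
        "test1B": _test1b,
        "test2B": _test2b,
        "test3A": _test3a,
        "table4_standard": lambda: table4_scenario(name="table4_standard"),
    }
    if name not in factories:
        raise ConfigurationError(
            f"unknown scenario {name!r}; available: {', '.join(BUILTIN_NAMES)}")
    return factories[name]()


def table4_sweep(variable: str = "scale", phases: str = "BRC",
                 modes: Iterable[str] = ("original", "scale_effect"),
                 ) -> List[Tuple[str, Scenario]]:
    """Labelled scenarios for one sweep of the case matrix.

    ``variable`` is "scale" (both dispersion modes by default),
    "porosity" or "rate" (scale-effect mode at the standard 0.5 m).
    """
    runs: List[Tuple[str, Scenario]] = []
    if variable == "scale":
        for mode in modes:
            for l0 in SCALE_SIZES:
                scn = table4_scenario(scale_size=l0, mode=mode, phases=phases)
                runs.append((f"L{l0:g}_{mode}", scn))
    elif variable == "porosity":
        for phi0 in POROSITIES:
            scn = table4_scenario(phi0=phi0, phases=phases)
            runs.append((f"phi{phi0:g}", scn))
    elif variable == "rate":
        for q1 in INJECTION_RATES:
            scn = table4_scenario(q1_ml_min=q1, phases=phases)
            runs.append((f"q{q1:g}", scn))
    else:
        raise ConfigurationError(
            f"unknown sweep variable {variable!r}; use scale, porosity or rate")
    return runs
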