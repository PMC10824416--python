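"""Treatment protocol driver: Phase B -> Phase R -> Phase C.

A :class:`Scenario` fully describes one simulation: column geometry,
medium/fluid/kinetic parameters, the dispersion settings, an ordered
list of :class:`PhaseSpec` stages and numerics options.  The runner
executes the phases in order, carrying the state, with the sequential
coupling  flow -> transport -> reaction -> precipitation  inside each
explicit step.  Everything is deterministic: two runs of the same
scenario are bit-identical.

Phases:

B -- bacterial suspension injected at constant rate from the source
     end; the opposite end is open at atmospheric pressure.
R -- retention: no flow, molecular diffusion and attachment only.
C -- cementation solution (urea/ammonium/calcium) injected, normally
     from the opposite end to Phase B; may be pulsed (each pulse period
     starts with injection of a fixed volume, followed by no-flow
     reaction for the rest of the period).

The urease-activity decay clock is anchored, by default, at the end of
the (first) bacterial injection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .dispersivity import DEFAULT_LAW, ScalingLaw, longitudinal_dispersivity, \
    transverse_dispersivity
from .errors import ConfigurationError
from .hydraulics import BoundaryConfig, FluidProps, DEFAULT_FLUID, solve_flow
from .kinetics import KineticParams
from .porosity_permeability import MediumParams, DEFAULT_MEDIUM, precipitate_step, \
    update_conductivity
from .state import ColumnState
from .transport import DispersionModel, admissible_dt, advance_solutes

#: Cross-sectional area (m^2) of the calibration column, chosen so that
#: the injected bacterial volume of the calibration test (442.1 mL)
#: equals one pore volume of the 0.5 m, phi0 = 0.37 column.  Roughly a
#: 5.5 cm diameter column.  All built-in scenarios reuse this area.
CALIBRATION_AREA = 442.1e-6 / (0.5 * 0.37)

_VALID_KINDS = ("B", "R", "C")
_VALID_FLOW = ("continuous", "pulsed", "none")
_SPECIES_BY_KIND = {"B": {"bacl"}, "C": {"urea", "ca", "nh4"}, "R": set()}


@dataclass(frozen=True)
class PhaseSpec:
    """One stage of the B/R/C protocol (all quantities SI).

    ``injected`` maps species names to injected concentrations:
    "bacl" in cells/mL for Phase B, "urea"/"ca"/"nh4" in mol/m^3 for
    Phase C.  For pulsed phases each ``pulse_period`` starts with
    injection of ``pulse_volume`` at ``rate`` followed by no flow.
    """

    kind: str
    duration: float
    flow_type: str = "continuous"
    rate: float = 0.0
    source_end: str | None = None
    injected: Mapping[str, float] = field(default_factory=dict)
    pulse_period: float | None = None
    pulse_volume: float | None = None

    def __post_init__(self):
        if self.kind not in _VALID_KINDS:
            raise ConfigurationError(f"phase kind must be one of {_VALID_KINDS}")
        if self.flow_type not in _VALID_FLOW:
            raise ConfigurationError(f"flow_type must be one of {_VALID_FLOW}")
        if self.duration < 0.0:
            raise ConfigurationError("phase duration must be >= 0")
        if self.kind == "R":
            if self.flow_type != "none" or self.rate != 0.0:
                raise ConfigurationError("Phase R is a no-flow retention stage")
        else:
            if self.flow_type == "none":
                raise ConfigurationError(f"Phase {self.kind} must inject fluid")
            if self.rate <= 0.0:
                raise ConfigurationError(f"Phase {self.kind} needs a positive rate")
            if self.source_end not in ("top", "bottom"):
                raise ConfigurationError(
                    f"Phase {self.kind} needs source_end 'top' or 'bottom'")
        allowed = _SPECIES_BY_KIND[self.kind]
        extra = set(self.injected) - allowed
        if extra:
            raise ConfigurationError(
                f"Phase {self.kind} cannot inject {sorted(extra)}; allowed {sorted(allowed)}")
        if any(v < 0.0 for v in self.injected.values()):
            raise ConfigurationError("injected concentrations must be >= 0")
        if self.flow_type == "pulsed":
            if not self.pulse_period or not self.pulse_volume:
                raise ConfigurationError(
                    "pulsed phase needs pulse_period and pulse_volume")
            if self.pulse_volume / self.rate > self.pulse_period:
                raise ConfigurationError(
                    "pulse_volume/rate exceeds pulse_period: no rest window")


@dataclass(frozen=True)
class Geometry:
    length: float
    area: float = CALIBRATION_AREA
    n_cells: int | None = None

    def __post_init__(self):
        if self.length <= 0.0 or self.area <= 0.0:
            raise ConfigurationError("geometry.length and geometry.area must be positive")
        if self.n_cells is not None and self.n_cells < 2:
            raise ConfigurationError("geometry.n_cells must be >= 2")


@dataclass(frozen=True)
class DispersionSpec:
    """Dispersion settings prior to resolution against the geometry.

    ``alpha_l = None`` in scale_effect mode means "evaluate the scaling
    law at the column length"; mode "original" forces alpha_l = 0.
    """

    mode: str = "scale_effect"
    alpha_l: float | None = None
    transverse_ratio: float = 10.0
    law: ScalingLaw = DEFAULT_LAW

    def __post_init__(self):
        if self.mode not in ("scale_effect", "original"):
            raise ConfigurationError(f"unknown dispersion mode {self.mode!r}")

    def resolve_alpha(self, scale_size: float) -> float:
        if self.mode == "original":
            return 0.0
        if self.alpha_l is not None:
            return self.alpha_l
        return longitudinal_dispersivity(scale_size, self.law)


@dataclass(frozen=True)
class Numerics:
    cfl: float = 0.9
    dif_number: float = 0.4
    snapshots_per_phase: int = 20
    urease_clock: str = "end_of_phase_B"

    def __post_init__(self):
        if not (0.0 < self.cfl <= 1.0 and 0.0 < self.dif_number <= 0.5):
            raise ConfigurationError("need 0 < cfl <= 1 and 0 < dif_number <= 0.5")
        if self.urease_clock not in (
                "end_of_phase_B", "start_of_phase_C", "start_of_simulation"):
            raise ConfigurationError(f"unknown urease_clock {self.urease_clock!r}")


def default_n_cells(length: float) -> int:
    """100 cells for the 0.5 m bench column, proportional up to 400."""
    return int(np.clip(round(200.0 * length), 100, 400))


@dataclass(frozen=True)
class Scenario:
    """Complete description of one simulation."""

    geometry: Geometry
    medium: MediumParams = DEFAULT_MEDIUM
    fluid: FluidProps = DEFAULT_FLUID
    kinetics: KineticParams = KineticParams()
    dispersion: DispersionSpec = DispersionSpec()
    phases: Sequence[PhaseSpec] = ()
    numerics: Numerics = Numerics()
    name: str = "scenario"

    def __post_init__(self):
        object.__setattr__(self, "phases", tuple(self.phases))

    @property
    def total_duration(self) -> float:
        return float(sum(p.duration for p in self.phases))

    def resolve(self) -> "Scenario":
        """Fill derived defaults (cell count, dispersivity from the law)."""
        geo = self.geometry
        if geo.n_cells is None:
            geo = replace(geo, n_cells=default_n_cells(geo.length))
        alpha = self.dispersion.resolve_alpha(geo.length)
        disp = replace(self.dispersion, alpha_l=alpha)
        return replace(self, geometry=geo, dispersion=disp)

    def dispersion_model(self) -> DispersionModel:
        alpha = self.dispersion.resolve_alpha(self.geometry.length)
        alpha_t = transverse_dispersivity(alpha, self.dispersion.transverse_ratio) \
            if alpha > 0.0 else 0.0
        return DispersionModel(alpha_l=alpha, alpha_t=alpha_t,
                               d_mol=self.fluid.d_mol, mode=self.dispersion.mode)


def initial_state(scn: Scenario) -> ColumnState:
    scn = scn.resolve()
    state = ColumnState.uniform(
        length=scn.geometry.length,
        area=scn.geometry.area,
        n_cells=scn.geometry.n_cells,
        phi0=scn.medium.phi_0,
        k0=scn.medium.k_0,
    )
    if scn.numerics.urease_clock == "start_of_simulation":
        state.urease_clock_start = 0.0
    return state


def build_phase_bcs(phase: PhaseSpec) -> BoundaryConfig:
    """Boundary configuration for a phase (injection window for pulsed).

    Phase B: inflow flux at the source end with the bacterial Dirichlet
    concentration, atmospheric pressure and zero dispersive flux at the
    outflow.  Phase R: no flow, atmospheric pressure at the top, zero
    dispersive flux everywhere.  Phase C: inflow with the cementation
    Dirichlet concentrations, outflow at atmospheric pressure.
    """
    if phase.kind == "R":
        return BoundaryConfig(rate=0.0, pressure_end="top")
    return BoundaryConfig(
        rate=phase.rate,
        source_end=phase.source_end,
        injected=dict(phase.injected),
    )


_REST_BC = BoundaryConfig(rate=0.0, pressure_end="top")


class _NullRecorder:
    def snapshot(self, *a, **k):  # pragma: no cover - trivial
        pass

    def accumulate(self, *a, **k):  # pragma: no cover - trivial
        pass


def _run_segment(state, bc, t_end, scn, model, recorder, phase_idx, snap_times):
    """Advance the coupled system under one boundary configuration."""
    duration_scale = max(t_end, 1.0)
    flow = solve_flow(state, bc, scn.fluid)
    ptr = 0
    while t_end - state.time > 1e-9 * duration_scale:
        q_cell = 0.5 * (flow.darcy_flux[:-1] + flow.darcy_flux[1:])
        flow.pore_velocity = q_cell / state.phi
        dt = admissible_dt(state, flow, model, scn.numerics.cfl,
                           scn.numerics.dif_number)
        while ptr < len(snap_times) and snap_times[ptr] <= state.time + 1e-9 * duration_scale:
            ptr += 1
        if ptr < len(snap_times):
            dt = min(dt, snap_times[ptr] - state.time)
        dt = min(dt, t_end - state.time)
        report = advance_solutes(state, flow, dt, model, scn.kinetics,
                                 scn.fluid, scn.medium, bc)
        converted = report.moles_converted(state)
        precipitate_step(state, report.k_rea_effective, dt, scn.medium, scn.fluid)
        update_conductivity(state, scn.medium)
        state.time += dt
        recorder.accumulate(report, state, converted)
        if ptr < len(snap_times) and state.time >= snap_times[ptr] - 1e-9 * duration_scale:
            recorder.snapshot(state, scn, bc, phase_idx, label="snap")
            ptr += 1
    return state


def run_phase(state: ColumnState, phase: PhaseSpec, scn: Scenario,
              recorder=None, phase_idx: int = 0) -> ColumnState:
    """Advance the state through one phase, emitting snapshots.

    A zero-duration phase returns the state unchanged.  Pulsed phases
    alternate injection windows (``pulse_volume`` at ``rate``) with
    no-flow rest windows inside each ``pulse_period``.
    """
    if recorder is None:
        recorder = _NullRecorder()
    if phase.duration <= 0.0:
        return state
    scn = scn.resolve()
    model = scn.dispersion_model()
    t0 = state.time
    t_end = t0 + phase.duration
    n_snap = scn.numerics.snapshots_per_phase
    snap_times = list(t0 + phase.duration * (np.arange(1, n_snap + 1) / n_snap))

    if phase.flow_type == "pulsed":
        bc_on = build_phase_bcs(phase)
        inject_dt = phase.pulse_volume / phase.rate
        pulse_start = t0
        while t_end - state.time > 1e-9 * max(t_end, 1.0):
            seg = min(pulse_start + inject_dt, t_end)
            _run_segment(state, bc_on, seg, scn, model, recorder, phase_idx, snap_times)
            seg = min(pulse_start + phase.pulse_period, t_end)
            _run_segment(state, _REST_BC, seg, scn, model, recorder, phase_idx, snap_times)
            pulse_start += phase.pulse_period
    else:
        bc = build_phase_bcs(phase)
        _run_segment(state, bc, t_end, scn, model, recorder, phase_idx, snap_times)
    return state


def run_scenario(scn: Scenario):
    """Execute all phases in order and collect a ResultSet.

    Axial profiles are recorded at a fixed cadence within each phase and
    at every phase boundary; breakthrough concentrations are recorded at
    the outflow face during flowing segments.  The run is deterministic.
    """
    from .results import Recorder  # local import to avoid a cycle

    scn = scn.resolve()
    state = initial_state(scn)
    rec = Recorder(scn)
    rec.snapshot(state, scn, None, phase_idx=-1, label="initial")
    for i, phase in enumerate(scn.phases):
        if scn.numerics.urease_clock == "start_of_phase_C" \
                and phase.kind == "C" and state.urease_clock_start is None:
            state.urease_clock_start = state.time
        run_phase(state, phase, scn, recorder=rec, phase_idx=i)
        rec.snapshot(state, scn, build_phase_bcs(phase), phase_idx=i,
                     label=f"{phase.kind}_end")
        if scn.numerics.urease_clock == "end_of_phase_B" \
                and phase.kind == "B" and state.urease_clock_start is None:
            state.urease_clock_start = state.time
    return rec.finalize(state)
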