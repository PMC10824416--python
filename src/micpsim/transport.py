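"""Advection-dispersion-reaction update for the mobile species.

Urea, calcium, ammonium and suspended bacteria obey

    phi dC/dt = d/dx(phi D* dC/dx) - q dC/dx + sources,

with the 1D hydrodynamic dispersion coefficient

    D* = alpha_L |v| + phi tau D,      tau = phi^(-1/3)

(Millington-Quirk tortuosity; the full dispersion tensor form is also
implemented and reduces to this in 1D).  Sources: ureolysis removes
urea and calcium one-for-one and releases two ammonium per urea;
suspended bacteria are lost to first-order decay and attachment.

Discretisation: cell-centred finite volume, first-order upwind
advection, central dispersion, explicit in time with the step bounded
by CFL <= 0.9, dispersive number <= 0.4 and a combined positivity
bound.  Reactions are operator-split after the transport update; within
a reaction substep urea conversion is clipped at the available urea,
the available calcium and the local clogging capacity, which keeps
every field non-negative and the stoichiometric ledger exact.

At the injection face the injected species hold their injected
concentration (Dirichlet: the face flux is the advective influx q C_in
plus a half-cell dispersive flux, so a strongly dispersive column can
draw in more than the pumped advective supply, as a fixed-concentration
reservoir does); species not carried by the injected fluid enter with
zero flux.  The outflow face is purely advective (zero dispersive
flux).  Closed faces carry no flux at all.  All boundary fluxes are
tallied, so the mass ledger is exact for every condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from .errors import DomainError, StabilityError
from .hydraulics import BoundaryConfig, FluidProps, FlowField, DEFAULT_FLUID
from .kinetics import BacteriaState, KineticParams, bacteria_step, urease_rate
from .porosity_permeability import MediumParams, DEFAULT_MEDIUM, max_reaction_capacity
from .state import ColumnState

SPECIES = ("urea", "ca", "nh4", "bacl")

CFL_LIMIT = 0.9
DIF_LIMIT = 0.4
POSITIVITY_LIMIT = 0.95


@dataclass(frozen=True)
class DispersionModel:
    """Hydrodynamic dispersion settings.

    mode "scale_effect" uses the mechanical term alpha_L |v|; mode
    "original" represents the classical treatment that ignored
    mechanical dispersivity, forcing alpha_L = alpha_T = 0 so only the
    tortuosity-corrected molecular term remains.
    """

    alpha_l: float = 0.0
    alpha_t: float = 0.0
    d_mol: float = 2.0e-9
    mode: str = "scale_effect"

    def __post_init__(self):
        if self.mode not in ("scale_effect", "original"):
            raise DomainError(f"unknown dispersion mode {self.mode!r}")
        if self.alpha_l < 0.0 or self.alpha_t < 0.0 or self.d_mol < 0.0:
            raise DomainError("dispersion lengths and D must be >= 0")
        if self.mode == "original":
            object.__setattr__(self, "alpha_l", 0.0)
            object.__setattr__(self, "alpha_t", 0.0)


def tortuosity(phi):
    """Millington-Quirk tortuosity tau = phi^(-1/3), for 0 < phi < 1."""
    p = np.asarray(phi, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise DomainError(f"porosity must lie in (0, 1), got {phi!r}")
    out = p ** (-1.0 / 3.0)
    return float(out) if np.isscalar(phi) else out


def dispersion_coefficient(v, phi, model: DispersionModel):
    """1D hydrodynamic dispersion D* = alpha_L |v| + phi tau D (m^2/s)."""
    tau = tortuosity(phi)
    out = model.alpha_l * np.abs(np.asarray(v, dtype=float)) \
        + np.asarray(phi, dtype=float) * tau * model.d_mol
    return float(out) if np.isscalar(v) and np.isscalar(phi) else out


def dispersion_tensor(v_vec, phi: float, model: DispersionModel) -> np.ndarray:
    """Full dispersion tensor (for completeness; the solver runs in 1D).

    D* = (alpha_L - alpha_T) v (x) v / |v| + alpha_T |v| I + phi tau D I.
    """
    v = np.asarray(v_vec, dtype=float)
    dim = v.size
    speed = float(np.linalg.norm(v))
    iso = (model.alpha_t * speed + phi * tortuosity(phi) * model.d_mol) * np.eye(dim)
    if speed == 0.0:
        return iso
    return (model.alpha_l - model.alpha_t) * np.outer(v, v) / speed + iso


@dataclass
class StepReport:
    """Book-keeping from one coupled step."""

    dt: float
    urea_converted: np.ndarray                 # mol per m^3 pore fluid, per cell
    influx: Dict[str, float] = field(default_factory=dict)    # amount entering column
    outflux: Dict[str, float] = field(default_factory=dict)   # amount leaving column

    @property
    def k_rea_effective(self) -> np.ndarray:
        """Realised ureolysis rate over the step (mol/m^3/s per cell)."""
        return self.urea_converted / self.dt

    def moles_converted(self, state: ColumnState) -> float:
        return float(np.sum(state.phi * self.urea_converted) * state.dx * state.area)


def admissible_dt(
    state: ColumnState,
    flow: FlowField,
    model: DispersionModel,
    cfl: float = CFL_LIMIT,
    dif: float = DIF_LIMIT,
) -> float:
    """Largest explicit step satisfying CFL, dispersive and positivity bounds."""
    v = np.abs(flow.pore_velocity)
    dstar = dispersion_coefficient(v, state.phi, model)
    dx = state.dx
    vmax = float(np.max(v))
    dmax = float(np.max(dstar))
    bounds = []
    if vmax > 0.0:
        bounds.append(cfl * dx / vmax)
    if dmax > 0.0:
        bounds.append(dif * dx * dx / dmax)
    combo = vmax / dx + 2.0 * dmax / (dx * dx)
    if combo > 0.0:
        bounds.append(POSITIVITY_LIMIT / combo)
    return min(bounds) if bounds else np.inf


def _species_fields(state: ColumnState) -> Dict[str, np.ndarray]:
    return {"urea": state.c_urea, "ca": state.c_ca,
            "nh4": state.c_nh4, "bacl": state.c_bacl}


def _face_fluxes(c, q, phi_d, dx, bc: BoundaryConfig | None, name: str) -> np.ndarray:
    """Conservative face fluxes F = qC - phi D* dC/dx, +x positive."""
    n = c.size
    flux = np.zeros(n + 1)
    face_pd = 0.5 * (phi_d[:-1] + phi_d[1:])
    upwind = c[:-1] if q >= 0.0 else c[1:]
    flux[1:-1] = q * upwind - face_pd * (c[1:] - c[:-1]) / dx

    if bc is None or bc.rate <= 0.0 or q == 0.0:
        return flux
    injected = bc.injected or {}
    c_in = float(injected.get(name, 0.0))
    dirichlet = name in injected
    if q > 0.0:  # inflow at the bottom face, outflow at the top face
        flux[0] = q * c_in
        if dirichlet:
            flux[0] += 2.0 * phi_d[0] / dx * (c_in - c[0])
        flux[n] = q * c[-1]
    else:        # inflow at the top face, outflow at the bottom face
        flux[n] = q * c_in
        if dirichlet:
            flux[n] -= 2.0 * phi_d[-1] / dx * (c_in - c[-1])
        flux[0] = q * c[0]
    return flux


def advance_solutes(
    state: ColumnState,
    flow: FlowField,
    dt: float,
    model: DispersionModel,
    kin: KineticParams,
    fluid: FluidProps = DEFAULT_FLUID,
    medium: MediumParams = DEFAULT_MEDIUM,
    bc: BoundaryConfig | None = None,
    reactions: bool = True,
) -> StepReport:
    """One explicit transport step plus operator-split reaction substep.

    Mutates ``state`` in place (concentrations only; porosity/calcite
    are updated separately by the precipitation step using the returned
    effective rate).  Refuses the step if ``dt`` exceeds the admissible
    bound, reporting the admissible value.
    """
    if dt <= 0.0:
        raise DomainError("dt must be positive")
    dt_adm = admissible_dt(state, flow, model)
    if dt > dt_adm * (1.0 + 1e-9):
        raise StabilityError(
            f"dt={dt:g}s exceeds admissible {dt_adm:g}s", admissible_dt=dt_adm)

    q = flow.q
    dstar = dispersion_coefficient(np.abs(flow.pore_velocity), state.phi, model)
    phi_d = state.phi * dstar
    dx = state.dx
    scale = dt * state.area  # amount = flux * area * dt

    report = StepReport(dt=dt, urea_converted=np.zeros(state.n_cells))
    for name, conc in _species_fields(state).items():
        flux = _face_fluxes(conc, q, phi_d, dx, bc, name)
        conc += dt / (state.phi * dx) * (flux[:-1] - flux[1:])
        np.maximum(conc, 0.0, out=conc)
        if q > 0.0:
            report.influx[name] = flux[0] * scale
            report.outflux[name] = flux[-1] * scale
        elif q < 0.0:
            report.influx[name] = -flux[-1] * scale
            report.outflux[name] = -flux[0] * scale
        else:
            report.influx[name] = 0.0
            report.outflux[name] = 0.0

    if reactions:
        bac = BacteriaState(c_bacl=state.c_bacl, c_bacs=state.c_bacs)
        k_rea = urease_rate(bac, state.c_urea, state.urease_elapsed, kin)
        delta = np.minimum(np.asarray(k_rea) * dt, state.c_urea)
        np.minimum(delta, state.c_ca, out=delta)
        np.minimum(delta, max_reaction_capacity(state, medium, fluid), out=delta)
        np.maximum(delta, 0.0, out=delta)
        state.c_urea -= delta
        state.c_ca -= delta
        state.c_nh4 += 2.0 * delta
        report.urea_converted = delta

        stepped = bacteria_step(bac, dt, kin)
        state.c_bacl = np.asarray(stepped.c_bacl)
        state.c_bacs = np.asarray(stepped.c_bacs)

    return report
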