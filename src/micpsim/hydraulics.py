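"""Fluid density, Darcy flow and the per-phase pressure solve.

The pore fluid density is an affine function of the dissolved urea,
calcium and ammonium,

    rho_l = rho_w + 0.0154994 C_urea + 0.0867338 C_Ca + 0.0158991 C_NH4

(concentrations in mol/m^3, coefficients in kg/mol), and the flux
follows Darcy's law q = -(K/mu) (dp/dx + rho_l g) on the vertical
column axis.

The default flow mode is quasi-incompressible: during an injection
phase the face flux is spatially uniform and equal to the injected
volumetric rate divided by the cross-sectional area, and the pressure
profile is recovered by integrating Darcy's law from the
atmospheric-pressure outlet.  The reaction mass sources of the full
continuity equation can optionally be retained ("full continuity"
mode); at column scale their contribution to q is far below the
injection flux.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from . import units
from .errors import ConfigurationError, DomainError
from .state import ColumnState

#: Density increments per unit concentration, kg/mol (affine density law).
DENSITY_COEFF_UREA = 0.0154994
DENSITY_COEFF_CA = 0.0867338
DENSITY_COEFF_NH4 = 0.0158991

P_ATM = 101325.0


@dataclass(frozen=True)
class FluidProps:
    """Fluid and mineral constants (defaults: water at 25 degC, calcite)."""

    rho_w: float = 1000.0       # kg/m^3
    mu_l: float = 1.0e-3        # Pa s
    d_mol: float = 2.0e-9       # molecular diffusion in water, m^2/s
    m_urea: float = 0.078       # kg/mol
    m_ca: float = 0.040         # kg/mol
    m_nh4: float = 0.018        # kg/mol
    m_caco3: float = 0.100      # kg/mol
    rho_c: float = 2710.0       # calcite density, kg/m^3
    g: float = 9.81             # m/s^2

    def __post_init__(self):
        for name in ("rho_w", "mu_l", "d_mol", "m_urea", "m_ca", "m_nh4",
                     "m_caco3", "rho_c", "g"):
            if getattr(self, name) <= 0.0:
                raise DomainError(f"fluid property {name} must be positive")


DEFAULT_FLUID = FluidProps()


@dataclass(frozen=True)
class BoundaryConfig:
    """Resolved boundary configuration for one treatment segment.

    ``rate`` is the injected volumetric rate (m^3/s, >= 0); zero means a
    no-flow segment.  ``source_end`` is the injection end ("top" or
    "bottom"); the opposite end holds atmospheric pressure with zero
    dispersive flux for every species.  ``injected`` maps species names
    ("bacl", "urea", "ca", "nh4") to injected concentrations; species
    absent from the map enter with zero concentration and zero
    dispersive flux.
    """

    rate: float = 0.0
    source_end: str | None = None
    injected: Mapping[str, float] | None = None
    pressure_end: str | None = None

    def __post_init__(self):
        if self.rate < 0.0:
            raise ConfigurationError("injection rate must be >= 0")
        if self.rate > 0.0:
            if self.source_end not in ("top", "bottom"):
                raise ConfigurationError(
                    "flowing boundary needs source_end 'top' or 'bottom', "
                    f"got {self.source_end!r}"
                )
            if self.pressure_end is not None and self.pressure_end == self.source_end:
                raise ConfigurationError(
                    "pressure end and flux end coincide: the flow problem is "
                    "over-determined at one end and under-determined at the other"
                )

    @property
    def outlet_end(self) -> str:
        if self.pressure_end is not None:
            return self.pressure_end
        if self.source_end == "bottom":
            return "top"
        if self.source_end == "top":
            return "bottom"
        return "top"

    @property
    def darcy_sign(self) -> float:
        """Sign of the Darcy flux on the bottom-up axis (+1 upward)."""
        return 1.0 if self.source_end == "bottom" else -1.0


@dataclass
class FlowField:
    """Pressure (per cell), Darcy flux (per face) and pore velocity."""

    pressure: np.ndarray
    darcy_flux: np.ndarray
    pore_velocity: np.ndarray

    @property
    def q(self) -> float:
        """Representative (inlet-face) Darcy flux, m/s, signed on the axis."""
        return float(self.darcy_flux[0])


def fluid_density(c_urea, c_ca, c_nh4, fluid: FluidProps = DEFAULT_FLUID):
    """Pore-fluid density rho_l (kg/m^3) from solute concentrations (mol/m^3)."""
    cu = np.asarray(c_urea, dtype=float)
    cc = np.asarray(c_ca, dtype=float)
    cn = np.asarray(c_nh4, dtype=float)
    if np.any(cu < 0.0) or np.any(cc < 0.0) or np.any(cn < 0.0):
        raise DomainError("concentrations must be >= 0")
    rho = (fluid.rho_w
           + DENSITY_COEFF_UREA * cu
           + DENSITY_COEFF_CA * cc
           + DENSITY_COEFF_NH4 * cn)
    scalars = all(np.isscalar(v) for v in (c_urea, c_ca, c_nh4))
    return float(rho) if scalars else rho


def state_density(state: ColumnState, fluid: FluidProps = DEFAULT_FLUID) -> np.ndarray:
    return fluid_density(state.c_urea, state.c_ca, state.c_nh4, fluid)


def solve_flow(
    state: ColumnState,
    bc: BoundaryConfig,
    fluid: FluidProps = DEFAULT_FLUID,
    p_atm: float = P_ATM,
    reaction_mass_source: np.ndarray | None = None,
) -> FlowField:
    """Darcy flux and pressure for the current state and boundary set-up.

    In the default quasi-incompressible mode the face flux is uniform,
    ``+/- rate/area`` on the bottom-up axis (zero in no-flow segments).
    Passing ``reaction_mass_source`` (kg/m^3/s per cell, the net fluid
    mass source of the continuity equation) activates the optional full
    continuity mode, in which the flux divergence balances the sources.
    The pressure is integrated from the atmospheric outlet using the
    per-cell conductivity, so a series of contrasting conductivities
    partitions the pressure drop in inverse proportion to them.
    """
    if np.any(state.phi <= 0.0) or np.any(state.k_cond <= 0.0):
        raise DomainError("flow solve requires positive porosity and conductivity")
    n = state.n_cells
    rho = state_density(state, fluid)

    q0 = bc.darcy_sign * bc.rate / state.area if bc.rate > 0.0 else 0.0
    q_face = np.full(n + 1, q0)
    if reaction_mass_source is not None and bc.rate > 0.0:
        # d(rho q)/dx = s  ->  integrate from the inlet face
        s = np.asarray(reaction_mass_source, dtype=float)
        increments = s * state.dx
        if bc.source_end == "bottom":
            q_face = (rho[0] * q0 + np.concatenate(([0.0], np.cumsum(increments)))) / \
                np.concatenate(([rho[0]], rho))
        else:
            rev = np.concatenate(([0.0], np.cumsum(increments[::-1])))[::-1]
            q_face = (rho[-1] * q0 - rev) / np.concatenate((rho, [rho[-1]]))

    # permeability from hydraulic conductivity: K = k mu / (rho_w g)
    k_perm = units.conductivity_to_permeability(1.0, fluid.mu_l, fluid.rho_w, fluid.g) \
        * state.k_cond
    # Darcy: q = -(K/mu)(dp/dx + rho g)  ->  dp/dx = -rho g - q mu / K
    q_cell = 0.5 * (q_face[:-1] + q_face[1:])
    grad = -rho * fluid.g - q_cell * fluid.mu_l / k_perm

    pressure = np.empty(n)
    if bc.outlet_end == "top":
        pressure[-1] = p_atm - grad[-1] * state.dx / 2.0
        for i in range(n - 2, -1, -1):
            pressure[i] = pressure[i + 1] - 0.5 * (grad[i] + grad[i + 1]) * state.dx
    else:
        pressure[0] = p_atm + grad[0] * state.dx / 2.0
        for i in range(1, n):
            pressure[i] = pressure[i - 1] + 0.5 * (grad[i - 1] + grad[i]) * state.dx

    v = q_cell / state.phi
    return FlowField(pressure=pressure, darcy_flux=q_face, pore_velocity=v)
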