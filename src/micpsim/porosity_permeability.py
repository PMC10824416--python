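"""Calcite accumulation, porosity loss and permeability feedback.

Each mole of urea hydrolysed removes one mole of Ca2+ from solution and
deposits one mole of immobile calcite, so per bulk volume

    dC_CaCO3/dt = m_CaCO3 * phi * k_rea,
    dphi/dt = -(1/rho_c) * m_CaCO3 * phi * k_rea,

which keeps the identity C_CaCO3 = rho_c (phi0 - phi) exact at all
times.  The hydraulic conductivity follows a Kozeny-Carman relation on
the effective porosity phi_e = phi - phi_c, where phi_c is the critical
porosity at which the pore network clogs:

    k(phi) = k0 * (phi_e / phi_e0)^3 * ((1 - phi_e0) / (1 - phi_e))^2.

Porosity is floored at phi_c; further precipitation in a clogged cell
is suppressed upstream (the reaction step caps local consumption) and
the cell is flagged.  For the flow solve the conductivity is floored at
1e-6 k0 rather than exactly zero to keep the problem well-posed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .hydraulics import FluidProps, DEFAULT_FLUID
from .state import ColumnState

log = logging.getLogger(__name__)

#: Relative conductivity floor applied in clogged cells.
CLOG_FLOOR = 1e-6


@dataclass(frozen=True)
class MediumParams:
    """Porous-medium parameters.

    phi_0 : initial porosity
    k_0 : initial hydraulic conductivity, m/s
    phi_c : critical (clogging) porosity
    a : Kozeny-Carman shape constant, used by the alternative power-law
        form ``k = k0 (phi_e/phi_e0)^(9a)``; the default effective-
        porosity form does not involve it
    kc_form : "effective" (default) or "power"
    """

    phi_0: float = 0.37
    k_0: float = 3.0e-4
    phi_c: float = 0.25
    a: float = 0.33
    kc_form: str = "effective"

    def __post_init__(self):
        if not (0.0 < self.phi_c < self.phi_0 < 1.0):
            raise DomainError(
                f"need 0 < phi_c < phi_0 < 1, got phi_c={self.phi_c}, phi_0={self.phi_0}"
            )
        if self.k_0 <= 0.0:
            raise DomainError("k_0 must be positive")
        if self.kc_form not in ("effective", "power"):
            raise DomainError(f"unknown Kozeny-Carman form {self.kc_form!r}")


DEFAULT_MEDIUM = MediumParams()


def kozeny_carman(phi, medium: MediumParams = DEFAULT_MEDIUM):
    """Hydraulic conductivity k(phi) in m/s; equals k_0 at phi_0, 0 at phi_c."""
    p = np.asarray(phi, dtype=float)
    tol = 1e-12
    if np.any(p < medium.phi_c - tol) or np.any(p > medium.phi_0 + tol):
        raise DomainError(
            f"porosity outside [{medium.phi_c}, {medium.phi_0}]: "
            f"range [{p.min()}, {p.max()}]"
        )
    p = np.clip(p, medium.phi_c, medium.phi_0)
    phie = p - medium.phi_c
    phie0 = medium.phi_0 - medium.phi_c
    if medium.kc_form == "power":
        k = medium.k_0 * (phie / phie0) ** (9.0 * medium.a)
    else:
        k = medium.k_0 * (phie / phie0) ** 3 * ((1.0 - phie0) / (1.0 - phie)) ** 2
    return float(k) if np.isscalar(phi) else k


def conductivity_floor(medium: MediumParams) -> float:
    return CLOG_FLOOR * medium.k_0


def update_conductivity(state: ColumnState, medium: MediumParams) -> None:
    """Refresh state.k_cond from the porosity field, applying the clog floor."""
    k = kozeny_carman(state.phi, medium)
    state.k_cond = np.maximum(k, conductivity_floor(medium))


def max_reaction_capacity(state: ColumnState, medium: MediumParams,
                          fluid: FluidProps = DEFAULT_FLUID) -> np.ndarray:
    """Per-cell urea moles (per m^3 pore fluid) convertible before clogging."""
    head = np.maximum(state.phi - medium.phi_c, 0.0)
    cap = fluid.rho_c * head / (fluid.m_caco3 * np.maximum(state.phi, 1e-30))
    return cap


def precipitate_step(
    state: ColumnState,
    k_rea: np.ndarray,
    dt: float,
    medium: MediumParams = DEFAULT_MEDIUM,
    fluid: FluidProps = DEFAULT_FLUID,
) -> ColumnState:
    """Deposit calcite for a reaction-rate field over one step (in place).

    ``k_rea`` is the effective ureolysis rate actually realised over the
    step (mol/m^3/s, already capped by reactant availability and the
    clogging limit), so the porosity floor is a safeguard rather than an
    active constraint.
    """
    if dt <= 0.0:
        raise DomainError("dt must be positive")
    rate = np.asarray(k_rea, dtype=float)
    if np.any(rate < 0.0):
        raise DomainError("reaction rate must be >= 0")
    d_caco3 = fluid.m_caco3 * state.phi * rate * dt
    d_phi = d_caco3 / fluid.rho_c
    head = state.phi - medium.phi_c
    over = d_phi > head
    if np.any(over):
        scale = np.where(over, np.maximum(head, 0.0) / np.maximum(d_phi, 1e-300), 1.0)
        d_caco3 = d_caco3 * scale
        d_phi = d_phi * scale
        newly = over & ~state.clogged
        if np.any(newly):
            log.warning("clogging reached in %d cell(s) at t=%.0f s",
                        int(np.sum(newly)), state.time)
        state.clogged |= over
    state.c_caco3 = state.c_caco3 + d_caco3
    state.phi = state.phi - d_phi
    return state
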