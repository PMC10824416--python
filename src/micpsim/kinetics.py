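"""Ureolysis and bacterial population kinetics.

Urease-producing bacteria hydrolyse urea at a Monod-limited rate that is
proportional to the total (suspended + attached) cell density and fades
exponentially as urease activity decays,

    k_rea = u_sp * (C_bacs + C_bacl) * C_urea / (C_urea + k_m) * exp(-t / t_d).

Both bacterial pools decay at a first-order rate k_d, and suspended
cells attach to grain surfaces at a first-order rate k_att:

    dC_bacl/dt = -(k_d + k_att) * C_bacl
    dC_bacs/dt = k_att * C_bacl - k_d * C_bacs.

The pair is linear, so :func:`bacteria_step` applies its exact
exponential solution over an arbitrary step; attachment is a pure
transfer and conserves C_bacl + C_bacs when k_d = 0.  There is no growth
term: during treatment the population only weakens.

Attached cells are stored on a pore-volume basis (cells per mL of pore
fluid) so that C_bacs + C_bacl in the rate law is dimensionally
consistent; :func:`attached_bulk_view` converts to a bulk-volume basis
for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the ureolysis/bacteria model.

    Defaults are the calibrated bench-column values:

    u_sp : maximum urease constant, mol/m^3/s per (cells/mL)
    k_m : Monod half-saturation of urea, mol/m^3
    t_d : urease-activity decay time constant, s
    k_d : bacterial decay rate, 1/s
    k_att : attachment rate, 1/s
    """

    u_sp: float = 1.4e-8
    k_m: float = 10.0
    t_d: float = 288000.0
    k_d: float = 3.18e-7
    k_att: float = 1.52e-3

    def __post_init__(self):
        for name in ("u_sp", "k_m", "t_d", "k_d", "k_att"):
            if getattr(self, name) < 0.0:
                raise DomainError(f"kinetic parameter {name} must be >= 0")


@dataclass
class BacteriaState:
    """Suspended (c_bacl) and attached (c_bacs) cell densities, cells/mL.

    Values may be scalars or per-cell arrays; both must be >= 0.
    """

    c_bacl: np.ndarray | float
    c_bacs: np.ndarray | float


def urease_rate(bac: BacteriaState, c_urea, t_elapsed: float, kin: KineticParams):
    """Monod ureolysis rate k_rea (mol/m^3/s).

    ``t_elapsed`` is the time since the urease-decay clock started
    (anchored by the scenario runner, by default at the end of bacterial
    injection).  The rate vanishes when either urea or bacteria vanish,
    and is monotone non-decreasing in each cell density and in urea.
    """
    c = np.asarray(c_urea, dtype=float)
    if np.any(c < 0.0):
        raise DomainError("urea concentration must be >= 0")
    if t_elapsed < 0.0:
        raise DomainError("elapsed time must be >= 0")
    total = np.asarray(bac.c_bacl, dtype=float) + np.asarray(bac.c_bacs, dtype=float)
    monod = np.divide(c, c + kin.k_m, out=np.zeros_like(c), where=(c + kin.k_m) > 0.0)
    decay = np.exp(-t_elapsed / kin.t_d) if kin.t_d > 0.0 else 1.0
    rate = kin.u_sp * total * monod * decay
    return float(rate) if np.isscalar(c_urea) and np.isscalar(bac.c_bacl) else rate


def bacteria_step(bac: BacteriaState, dt: float, kin: KineticParams) -> BacteriaState:
    """Advance decay and attachment by the exact linear-ODE solution.

    Closed form over a step of length ``dt``:

        C_bacl(dt) = C_bacl0 * exp(-(k_d + k_att) dt)
        C_bacs(dt) = exp(-k_d dt) * (C_bacs0 + C_bacl0 * (1 - exp(-k_att dt)))
    """
    if dt <= 0.0:
        raise DomainError(f"dt must be positive, got {dt!r}")
    cl0 = np.asarray(bac.c_bacl, dtype=float)
    cs0 = np.asarray(bac.c_bacs, dtype=float)
    decay = np.exp(-kin.k_d * dt)
    attach = np.exp(-kin.k_att * dt)
    cl = cl0 * decay * attach
    cs = decay * (cs0 + cl0 * (1.0 - attach))
    if np.isscalar(bac.c_bacl):
        return BacteriaState(c_bacl=float(cl), c_bacs=float(cs))
    return BacteriaState(c_bacl=cl, c_bacs=cs)


def attached_bulk_view(c_bacs, phi):
    """Attached cells per mL of bulk volume (reporting convenience)."""
    return np.asarray(c_bacs, dtype=float) * np.asarray(phi, dtype=float)
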