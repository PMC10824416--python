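"""Per-cell column state carried through a simulation.

The grid is fixed for the whole run: cell-centred, uniform spacing,
x = 0 at the column bottom and x = L at the top, with the column axis
vertical (gravity acts toward x = 0).  Injection may occur at either
end depending on the active treatment phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class ColumnState:
    """Arrays of the evolving fields plus the simulation clock.

    Concentrations: c_urea, c_ca, c_nh4 in mol/m^3 of pore fluid;
    c_bacl, c_bacs in cells/mL of pore fluid; c_caco3 in kg of calcite
    per m^3 of bulk volume.  ``k_cond`` is hydraulic conductivity (m/s).
    ``phi_initial`` keeps the starting porosity so the identity
    c_caco3 = rho_c * (phi_initial - phi) can be checked at any time.
    """

    x: np.ndarray
    dx: float
    area: float
    phi: np.ndarray
    k_cond: np.ndarray
    c_urea: np.ndarray
    c_ca: np.ndarray
    c_nh4: np.ndarray
    c_bacl: np.ndarray
    c_bacs: np.ndarray
    c_caco3: np.ndarray
    phi_initial: np.ndarray
    time: float = 0.0
    urease_clock_start: float | None = None
    clogged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.clogged is None:
            self.clogged = np.zeros_like(self.phi, dtype=bool)

    @property
    def n_cells(self) -> int:
        return self.x.size

    @property
    def length(self) -> float:
        return self.n_cells * self.dx

    @property
    def urease_elapsed(self) -> float:
        """Time on the urease-decay clock (zero before the clock starts)."""
        if self.urease_clock_start is None:
            return 0.0
        return max(0.0, self.time - self.urease_clock_start)

    def copy(self) -> "ColumnState":
        return replace(
            self,
            x=self.x.copy(),
            phi=self.phi.copy(),
            k_cond=self.k_cond.copy(),
            c_urea=self.c_urea.copy(),
            c_ca=self.c_ca.copy(),
            c_nh4=self.c_nh4.copy(),
            c_bacl=self.c_bacl.copy(),
            c_bacs=self.c_bacs.copy(),
            c_caco3=self.c_caco3.copy(),
            phi_initial=self.phi_initial.copy(),
            clogged=self.clogged.copy(),
        )

    @classmethod
    def uniform(
        cls,
        length: float,
        area: float,
        n_cells: int,
        phi0: float,
        k0: float,
    ) -> "ColumnState":
        """Homogeneous initial state: clean pore fluid, no bacteria."""
        dx = length / n_cells
        x = (np.arange(n_cells) + 0.5) * dx
        zeros = np.zeros(n_cells)
        return cls(
            x=x,
            dx=dx,
            area=area,
            phi=np.full(n_cells, float(phi0)),
            k_cond=np.full(n_cells, float(k0)),
            c_urea=zeros.copy(),
            c_ca=zeros.copy(),
            c_nh4=zeros.copy(),
            c_bacl=zeros.copy(),
            c_bacs=zeros.copy(),
            c_caco3=zeros.copy(),
            phi_initial=np.full(n_cells, float(phi0)),
        )

    def pore_moles(self, conc: np.ndarray) -> float:
        """Total amount in solution for a concentration field (per column)."""
        return float(np.sum(self.phi * conc) * self.dx * self.area)

    def total_caco3_mass(self) -> float:
        """Total precipitated calcite mass in the column (kg)."""
        return float(np.sum(self.c_caco3) * self.dx * self.area)
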