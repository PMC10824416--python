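"""Refitting the two calibrated kinetic constants.

The attachment rate k_att and the maximum urease constant u_sp are the
two medium-specific constants that cannot be taken from literature;
they are calibrated by least squares against a measured final calcite
profile.  The fit runs in log10 parameter space (both constants are
positive and span orders of magnitude) with residuals scaled by the
profile maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError
from .scheduler import Scenario, run_scenario


def simulated_carbonate(scn: Scenario, k_att: float, u_sp: float) -> np.ndarray:
    """Final calcite profile (kg/m^3 per cell) for the given constants."""
    scn2 = replace(scn, kinetics=replace(scn.kinetics, k_att=k_att, u_sp=u_sp))
    return run_scenario(scn2).final_state.c_caco3


@dataclass
class FitResult:
    k_att: float
    u_sp: float
    cost: float
    success: bool
    nfev: int


def fit_kinetics(
    scn: Scenario,
    observed_caco3: np.ndarray,
    initial: tuple[float, float],
    xtol: float = 1e-12,
    ftol: float = 1e-12,
) -> FitResult:
    """Least-squares recovery of (k_att, u_sp) from a calcite profile.

    ``observed_caco3`` must be sampled on the scenario's own grid.
    """
    obs = np.asarray(observed_caco3, dtype=float)
    scale = float(np.max(obs))
    if scale <= 0.0:
        raise DomainError("observed calcite profile is identically zero")
    k0, u0 = initial
    if k0 <= 0.0 or u0 <= 0.0:
        raise DomainError("initial guesses must be positive")

    def residuals(theta):
        k_att, u_sp = 10.0 ** theta
        return (simulated_carbonate(scn, k_att, u_sp) - obs) / scale

    sol = least_squares(residuals, x0=np.log10([k0, u0]), method="lm",
                        xtol=xtol, ftol=ftol)
    k_att, u_sp = 10.0 ** sol.x
    return FitResult(k_att=float(k_att), u_sp=float(u_sp),
                     cost=float(sol.cost), success=bool(sol.success),
                     nfev=int(sol.nfev))
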