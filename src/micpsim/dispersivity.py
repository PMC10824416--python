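"""Scale-size dependence of the longitudinal dispersivity.

Field and laboratory tracer studies show that the longitudinal
dispersivity of saturated porous media grows roughly as a power law of
the scale of observation.  In log-log space the relation is linear,

    log10(alpha_L) = slope * log10(L0) + intercept,

with alpha_L and the scale size L0 both in metres.  The default
coefficients (slope 0.88342, intercept -1.1267) come from a compilation
of published tracer data; they take alpha_L from about 1e-3 m at
L0 = 1e-2 m to about 1e4 m at L0 = 1e5 m.  The relation can be refitted
to a user-supplied compilation of (L0, alpha_L) points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import DegenerateFitError, DomainError

DEFAULT_SLOPE = 0.88342
DEFAULT_INTERCEPT = -1.1267

#: Standard hydrogeological convention: transverse dispersivity is one
#: tenth of the longitudinal value.
DEFAULT_TRANSVERSE_RATIO = 10.0


@dataclass(frozen=True)
class ScalingLaw:
    """Log-log linear relation between scale size and dispersivity.

    Both coefficients act in log10 space; ``alpha_L`` evaluations are in
    metres.  ``r_squared`` is populated by :func:`fit_loglog_relation`
    and is ``None`` for a law stated rather than fitted.
    """

    slope: float = DEFAULT_SLOPE
    intercept: float = DEFAULT_INTERCEPT
    r_squared: float | None = None

    def alpha_longitudinal(self, scale_size: float) -> float:
        return longitudinal_dispersivity(scale_size, self)


DEFAULT_LAW = ScalingLaw()


def longitudinal_dispersivity(scale_size, law: ScalingLaw = DEFAULT_LAW):
    """Longitudinal dispersivity alpha_L (m) for a given scale size L0 (m).

    Strictly increasing in ``scale_size`` whenever ``law.slope > 0`` and
    positive for every positive scale size.
    """
    l0 = np.asarray(scale_size, dtype=float)
    if np.any(l0 <= 0.0):
        raise DomainError(f"scale size must be positive, got {scale_size!r}")
    out = 10.0 ** (law.slope * np.log10(l0) + law.intercept)
    return float(out) if np.isscalar(scale_size) else out


def transverse_dispersivity(alpha_l: float, ratio: float = DEFAULT_TRANSVERSE_RATIO) -> float:
    """Transverse dispersivity alpha_T = alpha_L / ratio (m)."""
    if ratio <= 0.0:
        raise DomainError(f"transverse ratio must be positive, got {ratio!r}")
    if alpha_l < 0.0:
        raise DomainError(f"alpha_L must be non-negative, got {alpha_l!r}")
    return alpha_l / ratio


def fit_loglog_relation(points: Iterable[Tuple[float, float]]) -> ScalingLaw:
    """Ordinary least squares of log10(alpha_L) on log10(L0).

    Parameters
    ----------
    points
        Pairs ``(L0_m, alphaL_m)``, all strictly positive, at least two
        distinct ``L0`` values.

    Returns
    -------
    ScalingLaw with the fitted slope, intercept and R^2.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise DegenerateFitError("need at least two (L0, alpha_L) points")
    if np.any(pts <= 0.0):
        raise DomainError("all scale sizes and dispersivities must be positive")
    x = np.log10(pts[:, 0])
    y = np.log10(pts[:, 1])
    if np.unique(x).size < 2:
        raise DegenerateFitError("need at least two distinct L0 values to fit a slope")
    if np.ptp(y) == 0.0:
        # constant dispersivity: slope exactly zero, perfect fit
        return ScalingLaw(slope=0.0, intercept=float(y[0]), r_squared=1.0)
    res = stats.linregress(x, y)
    return ScalingLaw(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
    )


def read_points_csv(path) -> Sequence[Tuple[float, float]]:
    """Read a user compilation of (scale size, dispersivity) points.

    The file must be a two-column CSV with header ``L0_m, alphaL_m``.
    """
    import pandas as pd

    from .errors import ConfigurationError

    frame = pd.read_csv(path)
    required = {"L0_m", "alphaL_m"}
    if not required.issubset(frame.columns):
        raise ConfigurationError(
            f"dispersivity CSV must have columns {sorted(required)}, got {list(frame.columns)}"
        )
    return list(zip(frame["L0_m"].astype(float), frame["alphaL_m"].astype(float)))
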