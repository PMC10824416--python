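"""Shared fixtures: small, fast scenarios exercising the full protocol."""

import numpy as np
import pytest

from micpsim import (CALIBRATION_AREA, DispersionSpec, Geometry, KineticParams,
                     MediumParams, PhaseSpec, Scenario, units)


def mini_scenario(
    cells_per_ml: float = 7.2e5,
    k_d: float = 3.18e-7,
    k_att: float = 1.52e-3,
    u_sp: float = 1.4e-8,
    mode: str = "scale_effect",
    n_cells: int = 40,
    cement_hours: float = 2.0,
    name: str = "mini",
) -> Scenario:
    """A 0.1 m column treated with a shortened B/R/C protocol.

    Fast enough (a few hundred steps) for property tests and repeated
    calibration runs, while exercising every stage of the engine.
    """
    rate_b = units.ml_per_min_to_m3_per_s(10.0)
    rate_c = units.ml_per_min_to_m3_per_s(2.0)
    phases = (
        PhaseSpec(kind="B", duration=60e-6 / rate_b, flow_type="continuous",
                  rate=rate_b, source_end="bottom",
                  injected={"bacl": cells_per_ml}),
        PhaseSpec(kind="R", duration=1800.0, flow_type="none"),
        PhaseSpec(kind="C", duration=cement_hours * 3600.0,
                  flow_type="continuous", rate=rate_c, source_end="bottom",
                  injected={"urea": 300.0, "nh4": 300.0, "ca": 100.0}),
    )
    return Scenario(
        name=name,
        geometry=Geometry(length=0.1, area=CALIBRATION_AREA, n_cells=n_cells),
        medium=MediumParams(phi_0=0.37, k_0=3e-4),
        kinetics=KineticParams(u_sp=u_sp, k_d=k_d, k_att=k_att),
        dispersion=DispersionSpec(mode=mode),
        phases=phases,
    )


@pytest.fixture(scope="session")
def mini_result():
    from micpsim import run_scenario

    return run_scenario(mini_scenario())


@pytest.fixture
def rng():
    return np.random.default_rng(20240129)
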