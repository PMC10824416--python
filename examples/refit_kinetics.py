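"""Calibrate the two medium-specific kinetic constants from a profile.

The attachment rate k_att and maximum urease constant u_sp cannot be
taken from literature; they are fitted against a measured final calcite
profile.  Here the "measurement" is synthetic - generated by the
simulator itself with known constants - so the fit can be judged by how
exactly it recovers them.
"""

from micpsim import (CALIBRATION_AREA, Geometry, MediumParams, PhaseSpec,
                     Scenario, fit_kinetics, simulated_carbonate, units)

rate_b = units.ml_per_min_to_m3_per_s(10.0)
rate_c = units.ml_per_min_to_m3_per_s(2.0)
scn = Scenario(
    name="bench",
    geometry=Geometry(length=0.1, area=CALIBRATION_AREA, n_cells=30),
    medium=MediumParams(phi_0=0.37, k_0=3e-4),
    phases=(
        PhaseSpec(kind="B", duration=60e-6 / rate_b, rate=rate_b,
                  source_end="bottom", injected={"bacl": 7.2e5}),
        PhaseSpec(kind="R", duration=1800.0, flow_type="none"),
        PhaseSpec(kind="C", duration=5400.0, rate=rate_c,
                  source_end="bottom",
                  injected={"urea": 300.0, "nh4": 300.0, "ca": 100.0}),
    ),
)

true_katt, true_usp = 1.52e-3, 1.4e-8
observed = simulated_carbonate(scn, true_katt, true_usp)
print(f"synthetic observation: {observed.max():.1f} kg/m^3 peak calcite")

start = (true_katt * 1.4, true_usp * 0.7)
fit = fit_kinetics(scn, observed, initial=start)
print(f"start   : k_att={start[0]:.3g}  u_sp={start[1]:.3g}")
print(f"fitted  : k_att={fit.k_att:.4g}  u_sp={fit.u_sp:.4g} "
      f"({fit.nfev} forward runs)")
print(f"true    : k_att={true_katt:.4g}  u_sp={true_usp:.4g}")
print(f"recovery error: k_att {abs(fit.k_att/true_katt-1)*100:.2f}%, "
      f"u_sp {abs(fit.u_sp/true_usp-1)*100:.2f}%")
print("\nWith a clean profile both constants come back to well under 1%;")
print("on real data the residual reflects measurement and model error.")
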