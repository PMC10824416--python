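"""How far do injected bacteria reach at different treatment scales?

Runs the bacterial-injection phase of the case matrix at five scale
sizes, once with the molecular-diffusion-only dispersion of classical
models ("original") and once with the scale-dependent longitudinal
dispersivity.  The penetration ratio is the deepest point where the
suspended-bacteria concentration still exceeds 1e-3 of the injected
level, as a percentage of column height.
"""

from micpsim import (longitudinal_dispersivity, penetration_ratio,
                     run_scenario, table4_scenario)

print(f"{'L0 (m)':>7} {'alpha_L (m)':>12} {'original':>9} {'scale effect':>13}")
for l0 in (0.1, 0.5, 1.0, 5.0, 10.0):
    ratios = {}
    for mode in ("original", "scale_effect"):
        res = run_scenario(table4_scenario(scale_size=l0, mode=mode,
                                           phases="B"))
        ratios[mode] = penetration_ratio(res, "bacl", "B_end")
    print(f"{l0:>7g} {longitudinal_dispersivity(l0):>12.4g} "
          f"{ratios['original']:>8.1f}% {ratios['scale_effect']:>12.1f}%")

print("\nThe injected volume fills one pore volume of a 0.5 m column, so")
print("below that scale bacteria always break through (100%).  At larger")
print("scales the advective front stalls at 0.5 m and only dispersion")
print("carries cells deeper: ignoring the scale effect underestimates")
print("penetration, hence over-conservative treatment designs.")
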