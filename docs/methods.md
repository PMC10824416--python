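# Methods

This note records the model equations as implemented, the parameter
set, the numerical scheme, and the design choices made where the
problem statement left the design open.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Model

### Stages

A treatment is an ordered list of phases acting on one vertical column:

* **Phase B** — bacterial suspension injected at constant rate from one
  end; the opposite end is open at atmospheric pressure.
* **Phase R** — retention: no flow; molecular diffusion, attachment and
  decay only.
* **Phase C** — cementation solution (urea:NH4:Ca) injected, usually
  from the opposite end; optionally pulsed (each period starts with
  injection of a fixed volume, then no-flow reaction).

### Bacteria

Suspended cells `C_bacl` (cells/mL of pore fluid) are mobile; attached
cells `C_bacs` are immobile and stored on the same pore-volume basis so
the two densities add in the rate law (a bulk-volume view is available
for reporting).  Both pools decay at `k_d`; attachment transfers
suspended cells to the grains at `k_att`:

    dC_bacl/dt = −(k_d + k_att) C_bacl        (plus transport)
    dC_bacs/dt = k_att C_bacl − k_d C_bacs

The pair is linear, so the population substep applies its exact
exponential solution whatever the step size.  There is no growth term:
during treatment the population only weakens.

### Ureolysis

    k_rea = u_sp (C_bacs + C_bacl) · C_urea/(C_urea + k_m) · exp(−t/t_d)

`t` is measured on a urease-activity clock anchored, by default, at the
end of the bacterial injection (configurable to the start of Phase C or
of the simulation; the literature the rate constants descend from
clocks the decay from cell emplacement).  Ureolysis consumes urea and
Ca²⁺ one-for-one and releases two NH₄⁺ per urea; precipitated calcite
accumulates as `dC_CaCO3/dt = m_CaCO3 φ k_rea` with the porosity update
`dφ/dt = −dC_CaCO3/dt / ρ_c`, which makes the identity
`C_CaCO3 = ρ_c (φ0 − φ)` hold cellwise at all times (asserted in the
tests to 1e-10).

### Transport and dispersion

    φ ∂C/∂t = ∇·(φ D* ∇C) − q·∇C + sources
    D* = α_L |v| + φ τ D,   τ = φ^(−1/3),   v = q/φ

The full anisotropic dispersion tensor
`(α_L − α_T) v⊗v/|v| + α_T |v| I + φτD I` is implemented for
completeness and reduces to the scalar form in 1D; `α_T` defaults to
`α_L/10` (standard hydrogeological convention) and is irrelevant in 1D.
The longitudinal dispersivity is tied to the scale size by the log-log
law `lg α_L = 0.88342 lg L0 − 1.1267`; the coefficients are stored to
full printed precision and the law can be refitted by ordinary least
squares in log-log space from a two-column CSV of (L0, α_L) points.
"Original" mode represents the classical treatment that ignored
mechanical dispersivity: α_L = 0, leaving only the tortuosity-corrected
molecular term.  α_L is held constant through a run (the law ties it to
scale size, not to the evolving pore space); only the φτ factor of the
molecular term tracks porosity.

### Flow

Quasi-incompressible by default: during injection the Darcy flux is
spatially uniform, `q = ±Q/A`, and the pressure profile is recovered by
integrating `dp/dx = −ρ_l g − qμ/K` from the atmospheric outlet, with
`K = k μ/(ρ_w g)` converting the hydraulic conductivities the treatment
tables print into intrinsic permeabilities.  Buoyancy coupling through
the affine density law is always on.  The reaction mass sources of the
full continuity equation can be supplied to `solve_flow` (full
continuity mode) but are off by default: at column scale their
contribution to `q` is far below the injection flux.

### Porosity–permeability feedback

The conductivity follows an effective-porosity Kozeny–Carman relation,

    k(φ) = k0 · (φe/φe0)³ · ((1 − φe0)/(1 − φe))²,    φe = φ − φ_c,

which equals `k0` at the initial porosity and vanishes at the critical
porosity `φ_c` where the pore network clogs.  The exact published
variant behind the adopted constants is not recoverable from the
sources at hand, so the shape constant `a = 0.33` is carried in the
configuration and an alternative power-law form `k0 (φe/φe0)^(9a)` is
selectable; all calibration work uses the default form.  For the flow
solve, conductivity is floored at `1e-6 k0` in clogged cells to keep
the problem well-posed; reaction in a clogged cell is suppressed (the
conversion cap includes the remaining pore budget) and the cell is
flagged.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| ρ_w | water density (25 °C) | 1000 | kg/m³ |
| μ_l | viscosity (25 °C) | 1e-3 | Pa·s |
| D | molecular diffusion in water | 2e-9 | m²/s |
| m_urea, m_Ca, m_NH4, m_CaCO3 | molar masses | 0.078 / 0.040 / 0.018 / 0.100 | kg/mol |
| ρ_c | calcite density | 2710 | kg/m³ |
| u_sp | maximum urease constant | 1.4e-8 | mol/m³/s per cells/mL |
| k_m | Monod half-saturation | 10 | mol/m³ |
| t_d | urease-decay time constant | 288000 | s |
| k_d | bacterial decay rate | 3.18e-7 | 1/s |
| k_att | attachment rate | 1.52e-3 | 1/s |
| φ_c | critical porosity | 0.25 | – |
| a | Kozeny–Carman shape constant | 0.33 | – |

`u_sp` and `k_att` are the two medium-specific constants; `calibration.
fit_kinetics` refits them by Levenberg–Marquardt least squares (in
log10 space, residuals scaled by the profile maximum) against a final
calcite profile.

**Cross-sectional area.**  The bench protocols print injected volumes
and rates but not the column diameter.  The package fixes the area so
that the calibration column's injected bacterial volume (442.1 mL)
equals one pore volume of the 0.5 m, φ0 = 0.37 column:
`A = 2.3897e-3 m²` (≈ 5.5 cm diameter).  Every built-in scenario,
including the large-scale case matrix, reuses this area, so the Phase-B
advective front sits at 0.5 m at every scale.  This choice is
load-bearing for all quantitative comparisons and is a plain config
field (`geometry.area_m2`).

**Case-matrix source ends.**  The calibration column injects bacteria
from the top and cementation solution from the bottom; the parametric
case matrix injects both through the same bottom grouting port (the
single-port practice the matrix emulates — and the only arrangement
under which a 10 m column's cementation solution reaches the bacteria
within the treatment time).

## Numerics

* Cell-centred finite volume on a uniform grid, x = 0 at the column
  bottom; 100 cells for a 0.5 m column, proportionally more for longer
  ones, capped at 400 (i.e. `clip(round(200·L), 100, 400)`).
* First-order upwind advection, central dispersion, explicit time
  stepping with `dt` bounded by CFL ≤ 0.9, dispersive number ≤ 0.4 and
  a combined positivity bound `dt ≤ 0.95/(v/Δx + 2D*/Δx²)`; a step
  beyond the bound is refused with the admissible value reported.
* Operator splitting per step: transport, then ureolysis (conversion
  clipped at available urea, available calcium and the clogging
  budget — this keeps every field non-negative and the stoichiometric
  ledger exact), then the exact exponential bacteria update, then
  precipitation and the Kozeny–Carman refresh.
* Injection inlet: Dirichlet — the face flux is the advective influx
  `q C_in` plus a half-cell dispersive flux.  A consequence worth
  knowing: at high α_L the column can draw in more solute than the
  pumped advective supply, as a fixed-concentration reservoir permits.
  Species not carried by the injected fluid enter with zero flux.
  Outflow: advective only (zero dispersive flux).  All boundary fluxes
  are tallied, so mass ledgers close to round-off.
* The `φ ∂C/∂t` storage form (as modelled) means a porosity decrease
  leaves concentrations unchanged; solution inventories therefore drift
  relative to the flux ledger by at most the relative porosity loss
  (checked in the tests).  Conversion/production/calcite ledgers are
  exact by construction.
* Snapshots: 20 per phase plus phase ends; runs are bit-deterministic.

## Penetration metrics

The critical point of a species is the deepest location (from the
injection face, linearly interpolated between cell centres) where its
concentration still reaches ε; the penetration ratio is that depth over
the column height × 100.  "Zero" is numerically unattainable, so
ε defaults to 1e-3 × the injected concentration (1e-3 × the profile
maximum for species never injected, e.g. calcite); the threshold is a
library argument and a CLI flag, and the metric is monotone in it.
The scale-effect error measure is `δ = 100 (C_scale − C_orig)/C_orig`
applied to column averages or cumulative productions of paired runs; on
time series it is evaluated only once the reference exceeds 1% of its
final value (the ratio is ill-conditioned at the start of cementation).
The column-average conductivity reported after treatment is the
length-weighted harmonic mean of k(x) — the series value a constant-
head test on the whole column measures.

## What the built-in scenarios do and do not show

The built-in fixtures encode published bench protocols exactly (volumes,
rates, concentrations, durations, porosities, conductivities), and the
test suite reproduces the published porosity-sweep calcite maxima
within ±15%.  Three published quantities are *not* reproduced from the
printed parameter set, and the corresponding checks are deliberately
left failing rather than tuned:

* the calibration column's end-state conductivity (the printed kinetic
  constants bound total conversion below what the published value
  requires — the integrated urease capacity over the cementation phase
  is smaller than the calcium delivered);
* the original-mode penetration ratios at 1–10 m (with α_L = 0 the
  physical spreading beyond the one-pore-volume front is millimetres;
  the published critical points imply substantial additional numerical
  dispersion in the original study);
* the 10 m ammonium-production difference (it falls between the two
  physically available inlet regimes; see the inlet note above).

A closed-form advection–dispersion–decay estimate (Ogata–Banks with a
first-order sink) agrees with this simulator on all of these, which is
why the simulator, not the printed table, is trusted here.  Synthetic-
data self-consistency (parameter recovery, conservation, stoichiometry,
closed-form limits) is fully green; none of that guarantees agreement
with any particular laboratory column beyond the fidelity of the model
equations themselves.
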