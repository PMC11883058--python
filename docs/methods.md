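# Methods

This note documents the model implemented in `canopyresp`: its equations,
the parameter choices that matter, what the synthetic pieces emulate, the
numerical decisions, and the known limitations.

## Leaf physiology

**Base respiration rate.** Top-of-canopy leaf dark respiration at the
25 °C reference, acclimated to the recent thermal environment, is

    R_dark,top = max(0, r0 + r1·lnc_top + r2·t10)

with r1 = 0.2061 μmol CO₂ m⁻² s⁻¹ (gN m⁻²)⁻¹ and
r2 = −0.0402 μmol CO₂ m⁻² s⁻¹ °C⁻¹; r0 and the top-of-canopy leaf
nitrogen content lnc_top are PFT parameters. t10 is the mean of a rolling
10-day window of daily air temperature, pre-filled with the first day's
value at simulation start so the acclimated state is always defined. The
clamp at zero is ours: the linear form goes negative in hot, low-nitrogen
corners of parameter space and negative respiration is unphysical.

**Instantaneous temperature response.** The acclimated base rate is
multiplied by the decelerating log-polynomial

    ln(R_T / R_25) = 0.1012·(T − 25) − 0.0005005·(T² − 25²)

the standard global fit for the instantaneous temperature sensitivity of
leaf respiration: strictly increasing in T, but with declining
sensitivity at high temperature (concave in log space), unlike a fixed
Q10. The factor is applied uniformly over canopy depth; the simulator
carries no within-canopy temperature profile.

**Vertical scaling.** Both R_dark and V_cmax25 decay exponentially with
cumulative LAI from the top of the *patch* canopy:

    rate(L) = rate_top · exp(−k_n·L),    k_n = exp(a·V_cmax,25,top − b)

with a = 0.00963 and b = 2.43. Critically, an understory cohort's
uppermost leaves sit at the cumulative LAI of everything above them, not
at depth zero — this is what couples the vertical respiration gradient to
understory demography. The V_cmax profile always uses the default b; the
experiments rescale b for R_dark only (V1 = 1.2× … V8 = 0.5×), so the
R_dark/V_cmax25 ratio is depth-invariant exactly when the two decay
parameters coincide and declines with depth when the R_dark b is smaller.
V_cmax is not acclimated to t10; its instantaneous response is a standard
Arrhenius factor (activation energy 65.33 kJ mol⁻¹).

**Assimilation.** Gross assimilation per leaf layer is the co-limited
minimum of a Rubisco-limited rate A_c = V_cmax(T)·(C_i − Γ*)/(C_i + K_m)
— with fixed C_i = ci_over_ca·400 μmol mol⁻¹, Rubisco kinetics at 25 °C
(K_c = 404.9 μmol mol⁻¹, K_o = 278.4 mmol mol⁻¹, Γ* = 42.75 μmol mol⁻¹)
scaled by Arrhenius factors — and a light-limited rate
A_j = quantum_yield·APAR. There is no stomatal-conductance or
energy-balance solver; this preserves the light/capacity co-limitation
structure the trimming mechanism needs at a fraction of the cost.

## Light and the leaf-layer carbon budget

Incident PAR decays through the canopy as Beer–Lambert attenuation with
k_light = 0.5 (spherical leaf-angle distribution); a layer absorbs the
difference of incident flux across its boundaries, so absorbed plus
transmitted equals incident exactly. Canopy layers are 1.0 LAI unit thick
(configurable), with a partial deepest layer.

A layer's annual net carbon export (kg C m⁻² leaf yr⁻¹) is

    nce = assimilation − maintenance respiration − construction

Assimilation integrates the daytime rate over day_length hours per day,
multiplied by the diurnal-aggregation factor (below); respiration runs
24 h per day. Construction amortizes the carbon of one unit of leaf area
over the leaf lifespan: (1/SLA)/lifespan — the simplest dimensionally
consistent reading of "a function of leaf life span and specific leaf
area". Growth respiration is charged at the whole-plant level (0.11 of
the positive part of GPP minus maintenance respiration); a switch can
fold the same surcharge into the per-layer construction cost instead
(default off).

**Trimming.** Once per year a cohort compares the NCE of its deepest
retained leaf layer with zero: negative → the trim scalar on its target
leaf biomass drops by 0.05, positive (and trim < 1) → it recovers by
0.05, bounded to [0.3, 1]. The increment and floor are stable-convergence
choices (about 15 years from trim 1 to the floor). The LAI of maximum net
canopy export is also exposed directly as an exhaustive scan over
candidate LAIs in layer steps, ties broken toward the smaller LAI
(conservative canopy).

## Forcing

The synthetic generator emulates a lowland tropical climate: daily air
temperature = 26 °C mean + 1 °C seasonal sinusoid + stationary AR(1)
noise (sd 1 °C, lag-1 autocorrelation 0.6); daytime PAR = 1400 μmol
photons m⁻² s⁻¹ mean + 100 seasonal sinusoid, with multiplicative AR(1)
noise (sd 8 %) truncated at zero; day length fixed at 12 h. One integer
seed drives one dedicated random stream per series.

**Diurnal aggregation.** The simulator has no sub-daily resolution, so
daily assimilation is computed at the daytime characteristic PAR and
multiplied by day_length and a diurnal-aggregation factor of 2/π ≈ 0.637
— the closed-form ratio between a light-limited leaf's integral over a
sinusoidal photoperiod and a flat day at the same characteristic flux. A
flat 12-h day at full PAR would overestimate daily light-limited
assimilation by ~1/0.64 and, in particular, overstate the carbon balance
of shaded understory leaves, which are light-limited essentially all day.
Respiration is unaffected (it runs day and night on the acclimated
rates). What the generator does *not* emulate: humidity, rainfall, soil
moisture, cloud spells with realistic duration statistics, or the exact
seasonality of any particular station — so passing tests show the
mechanisms respond correctly to a plausible tropical climate, not that
any site's numbers are reproduced.

## Demography

**Cohorts and allometry.** Trees of one PFT and size are tracked as
cohorts (number density on a 1-ha patch). Power-law allometries give
height (2.0·dbh^0.6 m), crown area (0.2·dbh^1.3 m²), target leaf carbon
(trim·l1·dbh^1.3 kg C) and structural carbon (s1·dbh^2.5 kg C). Leaf and
crown share the same exponent, so a cohort's crown LAI is
trim·l1·SLA/c1 — size-independent, 6 at full trim for the shipped
tropical PFT. Trimming scales only the leaf target, never crown area, so
cohort LAI falls linearly in trim.

**Canopy layering.** Perfect-plasticity style: cohorts sorted by height
fill canopy layer 1 until summed crown area reaches the patch area; the
straddling cohort is split with densities partitioned; overflow fills
layers 2 and 3 (a three-layer cap, with any excess remaining in layer 3).
Light reaching a layer's top is the above-canopy PAR attenuated through
the patch-aggregated LAI of all layers above (no crown-scale
heterogeneity).

**Daily allocation.** Growth respiration is 0.11·max(0, GPP − R_maint);
NPP = GPP − R_maint − growth respiration. Carrying the trimmed allometric
leaf load is obligatory: leaf replacement toward the target is the first
claim on NPP and is flushed from storage when NPP cannot cover it; then
storage refills toward storage_target_fraction × target leaf carbon; the
remainder grows structure, advancing dbh by inverting the structural
allometry. Deficits draw storage down to zero. This ordering matters: if
storage were refilled first and leaf regrowth were optional, a shaded
tree could simply stop regrowing leaves and idle indefinitely at zero net
carbon with full reserves, and carbon starvation — the central understory
mechanism — could never occur. With obligatory leaf maintenance, chronic
shade drains reserves exactly as intended. Leaf turnover is continuous
(1/(lifespan·365) per day, one lifespan's worth per year); the
alternative annual abscission lump would make every year-end state an
unrepresentative post-abscission minimum.

**Mortality.** Annual rate m = background + cstarv_max·max(0, 1 −
storage/target); survival multiplies density by exp(−m). The linear ramp
with a cap (default cstarv_max = 0.2 yr⁻¹) is the simplest monotone form
for starvation mortality; its parameters are in the PFT table. Stem
maintenance respiration is a near-zero constant (10⁻⁶ yr⁻¹ per kg
structural C), deliberately mirroring the near-zero default of the host
models this simulator abstracts; there are no fine roots. Cohorts of the
same PFT *and canopy layer* within 5 % relative dbh are merged
density-weighted (restricting merges to a layer keeps depleted understory
reserves from being blended into canopy cohorts); cohorts below
10⁻³ individuals ha⁻¹ are removed.

**Recruitment.** One new cohort per PFT per year at dbh 1 cm with full
allometric pools. Two configurations, mirroring the two experiment
designs: *constant* seed rain (100 individuals ha⁻¹ yr⁻¹ — tropical
recruitment into the ≥1 cm class is of order 10²–10³ stems ha⁻¹ yr⁻¹) for
the single-PFT ensemble, and *NPP-linked* seed rain for the competition
experiment, where the rate is scaled by the PFT's patch-level NPP of the
closing year (full rate at 0.5 kg C m⁻² yr⁻¹, floor 2 % as external seed
rain). The NPP link matters for competition: with a PFT's seedling supply
independent of its carbon balance, the canopy-productivity advantage a
steep respiration gradient confers on a high-respiration PFT has no
demographic outlet, and the competition outcome inverts.

**Carbon ledger.** Every year the patch balances
ΔC_veg = GPP − R_maint − R_growth − litter − mortality losses +
recruitment inputs; the residual is recorded in the diagnostics and is at
machine precision (≲10⁻¹⁴ relative) in all shipped runs. Respiration a
completely carbon-empty tree cannot pay is subtracted from the realized
maintenance flux (such trees are dying at the maximal starvation rate).

## Experiments and shipped parameterizations

**Gradient ensemble.** Eight scenarios multiply the R_dark decay
parameter b by 1.2, 1.1, …, 0.5 (V1–V8). Each runs 150 years from bare
ground on identical seeded forcing with the single tropical PFT
(r0 = 1.62, lnc_top = 1.8 gN m⁻², V_cmax25,top = 41 — representative
broadleaf-evergreen-tropical values; their combination puts the emergent
top-of-canopy R_dark/V_cmax ratio at 0.023). Equilibrium diagnostics are
means over the final 10 years. 150 years suffices for LAI equilibrium at
this scale; equilibrium total and understory LAI rise monotonically with
gradient steepness (ties within forcing noise occur once LAI saturates at
its light-limited ceiling), leaf allocation is higher under V8 than V3,
and understory starvation mortality is non-monotone: high under shallow
gradients (respiration kills shaded trees), minimal at intermediate
steepness, rising again under the steepest gradients as the thickened
canopy makes the understory light-limited.

**Coexistence.** Four scenarios (V1, V3, V5, V7) run 300 years with two
PFTs on one patch under NPP-linked recruitment. The shipped
demonstration represents the case where the shade tolerant dominates
under the default gradient: a light-demanding pioneer (r0 = 2.2,
V_cmax25,top = 50, SLA 30 m² kgC⁻¹, 1-yr leaves, cheap wood s1 = 0.05,
background mortality 0.02, storage fraction 0.6) against a shade tolerant
(r0 = 1.2, V_cmax25,top = 35, SLA 14, 2.5-yr leaves, dense wood
s1 = 0.09, mortality 0.008, storage fraction 1.2). The pioneer's cheap,
short-lived leaves put the two PFTs' deep-shade construction costs near
parity (1/(SLA·lifespan): 0.033 vs 0.029 kg C m⁻² leaf yr⁻¹), so the
deep-shade margin is decided by respiration — which the steep gradients
relieve more for the high-r0 pioneer, in absolute terms, at every depth
(a closed-form canopy integral in the test suite). The pioneer's year-300
biomass share rises monotonically from V1 to V7, and the steep gradient
delays the shade tolerant's takeover by over a century — the delayed-
crossover pattern. These parameterizations are illustrative life-history
contrasts, not replicas of any calibrated set.

## Numerical choices

- Daily timestep; 365-day years; no leap days.
- The daily inner loop is vectorized across cohorts and leaf layers
  (padded arrays with an activity mask); a scalar reference path
  (`cohort_fluxes` + `allocate_npp`) defines the semantics and the test
  suite asserts the two agree to 10⁻⁹ relative over a full year.
- Cohort annual trim decisions reuse the layer-budget integrator with the
  daily PAR recorded at the cohort's canopy-layer top and the mean
  overlying LAI of its layer as the profile offset.
- Optimal-LAI ties break toward the smaller LAI; trim stays in
  [0.3, 1.0]; all pools are floored at zero.
- Degenerate inputs: an empty canopy yields an empty profile and empty
  budget list (trim unchanged); a bare patch runs with all fluxes zero;
  zero-PAR forcing gives zero assimilation everywhere.
- Output CSVs use a fixed numeric format (`%.10g`), making identical runs
  byte-identical.

## Limitations

- No light inhibition of leaf respiration (R_light): leaves respire at
  the dark rate around the clock. This overestimates total leaf
  respiration, most at the sunlit canopy top; the hook is the
  instantaneous-factor pipeline in `build_profile`.
- No water cycle, nitrogen cycle, stomatal optimization or hydraulic
  limitation; C_i/C_a is fixed.
- No fine roots and near-zero stem respiration, so NPP/GPP (CUE ≈
  0.55–0.75 in shipped runs) is high relative to observed forests;
  absolute GPP, biomass and allocation fluxes are likewise desk-scale
  quantities, not calibrated site values. Directional and ordering
  results across scenarios, not magnitudes, are the simulator's claims.
- One patch, no disturbance, fire, land use or patch-age dynamics; the
  understory light field is patch-aggregated (no crown-scale gaps).
- Sub-daily radiation structure is collapsed into the 2/π diurnal factor;
  sunlit/shaded leaf partitioning and diffuse/direct splitting are out of
  scope.
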