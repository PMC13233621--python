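# Methods

## Model

Each basin grid cell is a bistable tipping element in the fold normal
form, `dx/dt = −x³ + x + c`, with the forest state near x = −1 and the
open/degraded state near x = +1. The forest equilibrium is annihilated at
c\* = √(4/27); we treat forcing exactly at c\* as *not* tipped (strict
inequality), and experiments keep a margin around the threshold.

The total forcing of cell *i* has a local climatic part and a network
part.

**Local forcing.** Per hydrological year (October–September; partial
years at the series edges are dropped) we compute MAP (the 12-month
precipitation sum) and MCWD (the absolute minimum of the capped running
deficit `CWD_m = min(0, CWD_{m−1} + P_m − E_m)`, reset to zero each
October; a cross-year carry-over variant exists behind a flag). Forcing
snapshots use 10-year running means of both. With adaptation statistics μ
and Δ (mean and standard deviation of the per-year values over the
adaptation window) and the sampled capacity multiplier σ, the thresholds
are `MAP_crit = μ − σΔ_MAP` and `MCWD_crit = μ + σΔ_MCWD`. Each driver is
mapped linearly onto the forcing axis — zero at μ, c\* at the threshold,
negative (stabilizing) on the wet side. A reciprocal-ratio variant of the
MAP mapping shares those anchor points but diverges at MAP = μ and is
non-monotone across it; it is retained for comparison runs only
(`map_form="literal_reciprocal"`).

The standard deviation uses the population convention (divide by n): the
fixed adaptation window is treated as the cell's complete history
(`ddof=1` available). Cells with a vanishing adaptive range (σΔ = 0) have
no meaningful threshold; they are flagged non-tippable and clamped to the
forest state rather than given an arbitrary one.

**Combination of two drivers.** Components a, b combine as
`a + b − ab/c*`, the symmetric rewriting of `max + (1 − max/c*)·min`
(the max/min and lead-component case splits are algebraically
irrelevant). On [0, c\*]² this caps at c\*, with equality exactly when
the larger component reaches c\*. Beyond the threshold the product form
turns over — the cross term would *reduce* the combination and even make
it negative — so for max(a, b) ≥ c\* the larger component dominates
outright. This completion is continuous, monotone in both arguments, and
preserves the meaning of the cap: a driver past its critical value tips
the cell regardless of the other.

**Network coupling.** A directed link (k → i) carries monthly moisture
`m_ki` (mm/month). Over an evaluation window it is summarized by
ΔMAP_ki (mean annual delivery) and ΔMCWD_ki, computed counterfactually:
the target's MCWD is recomputed with the link's monthly deliveries
subtracted (precipitation clamped at zero), per hydro year, and the mean
deepening is taken — consistent with the windowed MCWD being a mean of
per-year values. A cheap proxy (link mass in deficit months) exists
behind `mode="deficit_month_proxy"`. The coupling
`R_ki = c*·ΔMAP_ki/(μ_MAP,i − MAP_crit,i)` (and the MCWD analogue,
combined like the local components) measures the link in units of the
target's safety margin: a link worth the full adaptive range has
R = c\*, i.e. losing it alone is tipping-equivalent.

**Activation.** Source k's coupling enters scaled by
`w(x_k) = (x_k + 1)/2`, clipped to [0, 1]: the withdrawn share
interpolates between intact forest (nothing withdrawn — the local
climate statistics already include delivered moisture) and the
transitioned state (all evapotranspiration gone). The clip matters
because the cubic's equilibria overshoot ±1 under forcing, and a cell
cannot lose more than all of its moisture; it also makes the ODE's
tipped sets consistent with the discrete cascade oracle. The printed
alternative `w(x) = x/2` (`coupling_baseline="literal_half_x"`) gives an
all-forest network a stabilizing baseline of −ΣR/2, which shifts the
calibrated thresholds; the zero-baseline form is the default precisely
because the thresholds are calibrated on the realized (moisture-
including) climate.

**Land use.** Cleared fractions f enter two ways: cells with f ≥ 0.5 are
held at x = +1 (reason `deforested`), and every cell's removed share
ρ = f·(1 − r) (r = evapotranspiration retained by secondary vegetation,
default 0) composes with the state activation as
`a = ρ + (1 − ρ)·w(x)` — moisture removed by clearing and by tipping
multiply. This form reduces to full removal at f = 1, to the pure state
term at f = 0, and is monotone in both f and x; scaling the outgoing
links by (1 − f) *instead* would make a fully cleared source contribute
no destabilization at all, i.e. more deforestation could produce fewer
transitions. `apply_landuse` (explicit link rescaling) is provided for
exogenous network preprocessing and the secondary-vegetation mode.
An optional guard mask (decadal MAP > 1,850 mm/yr and MCWD < 350 mm/yr,
AND by default) forbids safely wet cells from tipping in the
absolute-threshold robustness mode, with σ ∈ [0.50, 1.00] as the
companion bounds.

**Integration and cascade oracle.** Snapshots integrate all cells from
the all-forest state (x = −1, deforested cells held at +1) with
fixed-step RK4, dt = 0.1 model-time units, to t_max = 500, stopping when
‖dx/dt‖∞ < 1e−8; unconverged runs are flagged, never silent. The steady
state is a fixed point of the right-hand side and therefore independent
of dt; dt = 0.1 sits far inside RK4's stability region for this system
(|∂f/∂x| ≲ 4) and was chosen over smaller steps because only the
equilibrium is reported. Transition means x_final > 0. An independent
discrete oracle iterates the binary threshold cascade (tip any cell
whose forcing plus couplings from tipped/cleared sources strictly
exceeds c\*) to a fixed point in ≤ N passes; on margin-separated
networks the ODE and the oracle produce identical tipped sets, which the
test suite verifies on 200 random instances. Near the threshold the two
can legitimately differ: a continuum cell under partial forcing sits
slightly above −1 and leaks a small activation the binary oracle ignores,
which is why the equivalence experiment certifies each instance with a
root-finding fixed-point guard before comparing.

**Ensemble and attribution.** Per snapshot and member, σ is redrawn from
a `(master_seed, snapshot, member)` seed tuple (the per-decade redraw
reading of the ensemble design); with it thresholds, forcings and
couplings are rebuilt and the system re-integrated. Risk is the member
fraction transitioned per cell; transitioned area is area-weighted, both
relative to the basin (deforestation-forced cells included) and relative
to the initially forested area. Attribution: `deforested` for forced
cells (excluded from the three-way shares), else `map` if the MAP
component reached c\* (the larger component wins when both do), `mcwd`
likewise, else `network`. A transitioned cell with stabilizing local
forcing and no tipped or cleared in-neighbour is flagged as an
inconsistency.

## Synthetic study conditions

The generator emulates the statistical structure the analysis assumes,
not any particular dataset. Defaults (chosen once, on Amazon-like
magnitudes):

| parameter | default | rationale |
|---|---|---|
| baseline MAP | 2,200 mm/yr | humid tropical basin mean |
| seasonal amplitude | 120 mm/month | dry-season (Jun–Sep) deficit vs. 100 mm/month evaporation gives historical MCWD ~150–200 mm/yr |
| evaporation | 100 mm/month, constant | the conservative constant-ET level also used as a sensitivity mode |
| interannual s.d. | 450 mm/yr (~20% of MAP) | matches the scale at which losing 1 s.d. costs a quarter of annual rainfall |
| AR(1) φ | 0.3 | mild interannual persistence ("dry episodes") |
| spatial coherence | 0.8 of anomaly variance basin-common | ENSO-like basin-wide wet/dry years; keeps decadal-mean excursions inside the 0.75σ margin in a stationary climate |
| recycling cap | 0.5, building up downwind with a 6-cell e-fold | internal recycling approaches half of precipitation deep downwind and vanishes at the moisture-inflow edge, as in tracked precipitationsheds |
| transpiration share | 0.36 | stored as metadata only (the transpiration/interception split is not dynamically modelled) |
| kernel | exponential, 1.5-cell e-fold, displaced one cell downwind, mild lognormal jitter | short-range downwind-biased deposition |
| drying presets | 0 / −30 / −60 mm/yr/decade (+ dry-season deepening −1.5 / −3 mm/month/decade), weighted 1.4× upwind | produce committed transitions emerging mid-to-late century, ordered by severity |
| deforestation | 18% → 35% basin clearance 2021–2050, logistic front from the upwind edge, then constant | severe reference trajectory; road-pattern spatial detail is not reproduced |

The scenario *branches off* the historical realization: one continuous
climate run spans 1950–2100 with trends switched on in 2020, so the
adaptation statistics and the early scenario share the same anomaly
process and the branch point carries no spurious forcing offset. For
controlled monotonicity experiments, `noise_free_scenario=True` replaces
the scenario segment with a deterministic run anchored to the realized
historical mean. Monthly precipitation is clipped at zero, so extreme
nominal drying saturates once dry months bottom out.

What the generator does **not** emulate: spatially structured
(road-driven) deforestation, climate–vegetation feedback onto the
prescribed P/E fields (the design is offline, as in the original
experiment), moisture-tracking physics, sub-monthly water balance, and
any real geography. Passing tests therefore demonstrate the *machinery*
— metric definitions, threshold calibration, cascade dynamics,
bookkeeping — under controlled conditions, not quantitative realism for
any basin.

A note on regime: with recycling approaching 0.5 downwind, per-cell
coupling sums reach the order of the tipping threshold itself, so the
basin is strongly supercritical — once local forcing erodes a fraction
of the safety margin, cascades sweep large contiguous areas within one
snapshot. The transitioned-area trajectories are accordingly steep, and
the cascading (`network`) share of attributed transitions dominates.
That is the intended phenomenology of a tightly coupled
moisture-recycling basin, not an artifact.

## Numerical choices and degenerate inputs

- RK4 dt = 0.1, t_max = 500, residual 1e−8, convergence checked every 25
  steps; tie at c = c\* treated as not tipped.
- Missing months inside a hydrological year are a hard error (no
  imputation); incomplete leading/trailing years are dropped with a
  warning when none remain.
- Deforestation fronts solve the logistic front position by bisection to
  an area tolerance ≈1e−10 of basin area; per-cell fractions are made
  exactly non-decreasing in time.
- Link-removal counterfactuals clamp precipitation at zero and warn if a
  link exceeds its target's precipitation (impossible for generated
  networks, possible for hand-edited inputs).
- σ sampling in the wetness-scaled modes interpolates in basin
  percentile rank (grid-size invariant), with ties averaged; a single
  cell gets the midpoint.
- Windowed means label each window by the year at offset `window // 2`
  from its start (2021–2030 → 2026) and drop incomplete windows.

## Problem sizes

The ensemble experiments use a 20 × 20 grid, 10 members and 8 decadal
snapshots (2020s–2090s) — the configuration of the monotonicity and
attribution suites; unit tests use smaller grids. Historical window
1950–2014 (64 complete hydrological years), scenario 2020–2100.

## Known limitations

- Hysteresis and recovery under reversed forcing are not simulated;
  snapshots are independent committed-equilibrium runs, so relaxing
  climate *can* reduce later snapshots' transitioned area by design.
- The transition timescale is not calibrated: model time units are
  arbitrary, and only equilibria are interpreted.
- With noisy scenario climate, rare basin-wide drought decades can
  exceed the 0.75σ margin and trigger cascades in a statistically
  stationary climate; the controlled experiments therefore use the
  noise-free configuration, and noisy runs should be read as risk
  estimates, not determinations.
- The attribution is threshold-based on the local components; a cell
  pushed over jointly by near-threshold local forcing and a small
  network contribution is counted as `network`.
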