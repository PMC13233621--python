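# tipcascade

Committed forest transitions on a directed moisture-recycling network.

Tropical forests recycle a large share of their own rainfall: moisture
evapotranspired by one region falls again as precipitation downwind. When a
forest patch dies back or is cleared, that delivery stops, pushing downwind
forest closer to its own drought limits — transitions can therefore
*cascade* along the wind. `tipcascade` implements this coupled
tipping-element analysis end to end for users studying forest–rainfall
feedback: hydrologists and ecologists who want to map committed transition
risk under drying and deforestation scenarios, and modellers who want a
transparent, fully synthetic testbed for cascade dynamics on
moisture-recycling networks.

## Model

Each grid cell *i* is a bistable element in the normal form of a fold
bifurcation (x = −1 forest, x = +1 open/degraded state):

```
dx_i/dt = −x_i³ + x_i + C_crit,i(MAP_i, MCWD_i) + Σ_k R_ki · w(x_k)
```

The uncoupled cell tips exactly when its total forcing exceeds
c\* = √(4/27) ≈ 0.3849. Two hydrological drivers force each cell, both
measured per hydrological year (October–September) and averaged over
10-year windows:

- **MAP** — annual precipitation (mm/yr);
- **MCWD** — maximum cumulative water deficit, the deepest value of the
  capped running deficit `CWD_m = min(0, CWD_{m−1} + P_m − E_m)`, reported
  as a positive magnitude (mm/yr).

Cells are assumed adapted to their local history: with mean μ and
interannual standard deviation Δ over the adaptation window (1950–2014),
the critical thresholds are `MAP_crit = μ_MAP − σΔ_MAP` and
`MCWD_crit = μ_MCWD + σΔ_MCWD`, where the adaptive-capacity multiplier σ is
drawn uniformly from [0.75, 1.25] per cell and ensemble member. Each driver
maps linearly onto the forcing axis (0 at μ, c\* at the threshold) and the
two components a, b combine as `a + b − ab/c*`, which caps at c\* — a
single driver at threshold is exactly tipping-equivalent to any mixture at
threshold. Each moisture link carries an analogous coupling
`R_ki = c*·ΔMAP_ki/(σΔ_MAP,i)` (combined with its MCWD counterpart), the
share of cell i's safety margin that cell k's moisture delivery is worth;
`w(x) = (x+1)/2` (clipped to [0, 1]) activates it as the source
transitions, and cleared land contributes its cleared fraction the same
way. Transition risk is the fraction of Monte Carlo members in which a
cell ends transitioned, and every transition is attributed to `map`,
`mcwd`, `network` (cascading moisture loss) or `deforested`.

A synthetic scenario generator replaces external climate-model and
moisture-tracking products: seasonal monthly P/E with basin-coherent AR(1)
interannual variability, drying trends weighted toward the upwind edge,
downwind-biased recycling networks whose internal recycling fraction
builds up along the wind to ~0.5, and a logistic deforestation front
(18% → 35% basin clearance over 2021–2050 in the reference trajectory).

## Worked example

```python
import tipcascade as tc

bundle = tc.generate_scenario("moderate_drying", nx=10, ny=10, seed=0,
                              noise_free_scenario=True)
result = tc.run_ensemble(bundle, n_members=10, n_snapshots=8, master_seed=1)
print(result.area_frame().to_string(index=False))
```

```
 snapshot_label  area_mean_pct  area_sd_pct  area_forest_rel_mean_pct  deforested_pct
           2020            0.0          0.0                       0.0             0.0
           2030            0.0          0.0                       0.0             0.0
           2040            0.0          0.0                       0.0             0.0
           2050           97.3          1.7                      97.3             0.0
           2060          100.0          0.0                     100.0             0.0
           2070          100.0          0.0                     100.0             0.0
           2080          100.0          0.0                     100.0             0.0
           2090          100.0          0.0                     100.0             0.0
```

Each row is one decadal snapshot (labelled by its first hydrological
year), integrated to its *committed* equilibrium: the transitioned area if
that decade's climate persisted indefinitely. Under this moderate drying
the basin holds for three decades, then tips almost completely within one
decade — the member spread (`area_sd_pct`) is wide only in the transition
decade, where the outcome still depends on the sampled adaptive
capacities. Summing the attribution counts over snapshots and members:

```
map          0    0.0%
mcwd      1090   21.9%
network   3883   78.1%
```

MCWD crossings trigger the first transitions; more than three quarters of
all transitioned cells fall as cascades — they tip only because upwind
cells stopped delivering moisture, the signature of a strongly coupled
recycling network.

A command-line pipeline wraps the same functions
(`tipcascade synth | metrics | adapt | simulate | attribute | riskplane |
verify`); every run writes a JSON manifest with config and seeds.

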