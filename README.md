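# swanstage

An individual-based stopover model of Bewick's swans (*Cygnus columbianus
bewickii*) foraging on fennel pondweed (*Potamogeton pectinatus*) tubers in a
shallow freshwater lake whose water level is held at a management target by a
tide-gated sluice. The package is for ecologists and water managers who want
to ask: **how many migratory swans can a managed lake support in autumn, and
what happens to that number when the target water level changes?**

Swan usage of such a lake is not a simple division of standing food by
per-bird consumption. Tubers are buried, so the reachable fraction depends on
hourly water depth; intake saturates with food density and is depressed by
interference between foragers; depletion and individual energy stores decide
who stays and who leaves. Because these processes interact, the response of
peak numbers and total bird-days to a change in water regime emerges from the
simulation — and it is strongly nonlinear.

## The model

Time steps are hourly over a two-month season. Each agent is a
super-individual of 20 swans sharing one state (location, energy store).

**Water.** The lake can only be drawn down toward the target level when the
sea side of the sluice is lower than the lake (drawdown 0.15 m h⁻¹); otherwise
hinterland inflow raises it (0.01 m h⁻¹). Around neap tide drawdown can be
blocked for days and the lake rides up above its target. Patch water depth is
the patch's standardized depth plus the current level anomaly.

**Foraging.** On a patch with tuber density *D* (g m⁻²), sediment *s* and
actual depth *d*, per-swan intake is a type II functional response,

    I = f · b · i(N) · φ(s) · a(s) · A(d) · D / (1 + a(s) · h · A(d) · D)

with time budget *f*, area-restricted-search benefit *b*, interference
polynomial *i(N)* in swans m⁻², time-underwater fraction φ, attack rate *a*,
handling time *h*, and the accessible fraction *A(d)* — 1 up to the
head-dipping limit (0.51 m), 0 beyond maximum reach (0.86 m), falling off
quadratically in between via a sediment-specific burial-depth factor. The net
gain rate is

    G_t = q · e · I − (f · c_f + (1 − f) · (c_r + c_p)/2)

**Decisions.** Swans have perfect knowledge and maximize the expected gain
rate, counting themselves in patch density; moves between inlets cost one hour
and one fixed 53 kJ flight. A swan departs when its store reaches the target
(≈49 MJ, body condition at abdominal profile 5), and abandons the lake for the
surrounding sugar-beet fields when the best obtainable gain drops below
p·(MEI_b − DEE_b)/86400 ≈ 36.8 J s⁻¹. Arrivals come in two normal peaks
(SD 3 days) 14 days apart, the second half the size of the first.

Every input the field study measured (tidal forcing, patch table, arrival
schedule, observed counts) has a synthetic generator with the study's
statistical structure, so the full pipeline runs with no external data.

## Worked example

```python
from swanstage import (ModelParams, SluiceModel, gain_rate, emigration_threshold,
                       run_simulation, simulate_lake_level, summarize_replicates,
                       year_schedule)
from swanstage.engine import derive_seed
from swanstage.synth import study_forcing, synth_patches

params = ModelParams()          # published parameter set
g = gain_rate(D=13.2, sediment="sand", depth_class="shallow", d=0.33, N=0.0,
              params=params)
print(f"net gain on a fresh sandy-shallow patch: {g.net_J_s:.1f} J/s")
print(f"emigration threshold: {emigration_threshold(params):.1f} J/s")

sea = study_forcing(2005)                       # synthetic tidal forcing
lake = simulate_lake_level(sea, SluiceModel())  # managed lake levels
patches = synth_patches(2005, se_scale=0.0)     # measured mean densities
runs = [run_simulation(params, patches, lake, year_schedule(2005, 4500),
                       seed=derive_seed(1, 0, r)) for r in range(4)]
s = summarize_replicates(runs)
print(f"peak number: {s.peak_mean:.0f} +/- {s.peak_sd:.0f} swans")
print(f"bird-days:   {s.bird_days_mean:.0f} +/- {s.bird_days_sd:.0f}")
```

prints

```
net gain on a fresh sandy-shallow patch: 98.8 J/s
emigration threshold: 36.8 J/s
peak number: 1855 +/- 102 swans
bird-days:   15270 +/- 1089
```

A fresh sandy-shallow patch yields about 99 J s⁻¹ net, far above the 36.8
J s⁻¹ giving-up threshold, so arriving swans settle there; over the season
4500 arriving swans produce ~15 000 bird-days and a peak count near 1900,
staging about 3 days each — the same regime the field counts showed. Raising
the sluice target by 0.20 m (`sweep_target_levels`) pushes even the shallow
patches past the head-dipping depth most hours and collapses bird-days by
~97%, while lowering it 0.10–0.20 m changes little: the nonlinear threshold
response that makes water-level policy consequential for this site.

The `analysis/` directory holds the numbered drivers that run the whole
study on synthetic inputs (generate inputs, fit sluice rates, simulate the
four seasons, calibrate incoming totals, sweep target levels, parameter
elasticities); each writes its tables under `results/`. A `swanstage` CLI
exposes the same steps (`swanstage --help`).

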