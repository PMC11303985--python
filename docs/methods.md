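# Methods

## The behavioral model

A fish population's behavior is reduced to one state variable per time
step: the predation-mitigation level `p ∈ [0, 1]`. The model is agnostic
about which concrete behaviors (refuge use, reduced activity, schooling)
realize mitigation; their aggregate effect is assumed linear in `p` on
both sides of the trade-off. Mitigation reduces feeding activity
(`f_feed = 1 − p·f_FC`), predation mortality (`m_tot = m_nat +
(1 − p·f_PM)·m_pred.s`), and — through `f_feed` — the feeding-linked part
of metabolism (`u_tot = (1 + f_RF·f_feed)·u`).

Feeding is gut-limited: encountered prey fills gut capacity at the rate
`f_feed·f_veg·c·f_gut·R` against the processing capacity `I_max`, giving a
feeding (satiation) level `F` in `[0, 1)` and the assimilation rate
`g = a·f_feed·f_veg·c·R·(1 − F)`. With `f_feed = 1` this is algebraically
a Holling type II response whose handling time is `f_gut/I_max` and attack
rate `f_veg·c`; the gut formulation is preferred because it extends
naturally to mixed diets of unequal quality. The hunger factor `1 − F` is
computed as `I_max/(I_max + load)` rather than by subtraction, which keeps
the type II identity exact (≲1e-15 relative) even at near-saturation.

Fitness is Gilliam's rule, net specific energy gain over total mortality,
`W = (g − u_tot)/m_tot` — equal to lifetime reproductive output in a
stable environment. The ratio is used whenever feeding at `p = 0` would
yield a non-negative net gain (`g_pot ≥ u_pot`). Otherwise survival is
limited by starvation rather than predation and the proxy degrades to the
net gain itself, with two sub-cases decided by whether feeding pays its
own marginal cost: keep feeding maximally while `g_pot − u_pot > −u`
(equivalently `g_pot > f_RF·u`; not feeding yields `−u`, so this is the
Gilliam-consistent comparison), otherwise stop feeding entirely
(`f_feed = 0`), which frees the fish to mitigate fully (`p* = 1`).

### Exact optimization

In the normal regime `W(p)` is a smooth rational function on `[0, 1]`:
with `D(p) = I_max + E·f_feed` (where `E = c·f_gut·f_veg·R`), the numerator
of `W'(p)` times `D(p)²` is a cubic polynomial in `p`. The solver evaluates
`W` at the real cubic roots inside `(0, 1)` plus both endpoints and returns
the argmax — an exact global optimization, verified against an independent
dense-grid (10⁴ points) plus golden-section oracle to ≲1e-12 relative over
wide log-uniform parameter draws. Plateaus flatter than 1e-12 resolve to
the largest `p` (mortality weakly decreases in `p`, so the largest
maximizer is the safest). Regime thresholds compare specific rates with
absolute tolerance 1e-12 d⁻¹. `m_nat > 0` is required (and enforced by
config validation) so the ratio's denominator never vanishes.

### Risk smoothing

The predation risk entering the decision is exponentially smoothed,
`m_s ← (m_s_prev + 0.25·m_pred)/1.25`, i.e. a per-step relaxation factor
of 0.8 toward the instantaneous rate. This prevents erratic step-to-step
switching of predator and prey efforts and compensates for the
unrealistically fast reaction a daily decision cadence would otherwise
imply. The filter's fixed point is the constant input, and convergence
from rest follows `1 − 0.8ⁿ` exactly.

## Multi-prey feeding

Three decisions are made independently and in fixed order, before the
behavioral decision: diet composition within each feeding mode, allocation
among modes, then overall effort. Weighing modes against each other in
terms of differential predation exposure would require knowledge rarely
available, so modes receive weights proportional to the ingestion each
would yield at maximized feeding; if all modes yield zero the weights are
uniform.

Within a mode, diet breadth follows the contingency-model zero-one rule:
prey ranked by profitability `a_i/f_gut_i` (assimilated energy per unit of
the binding gut constraint; ties broken by larger encounter `c_i·R_i`),
added while total assimilation increases. Because the aggregate
assimilation is a ratio of sums monotone in this ranking, the greedy diet
equals the exhaustive subset optimum — asserted against brute force in
tests. Prey with `f_gut = 0` cost no gut capacity and are always included.

Because diets change iteratively, they cannot enter the closed-form `p*`
directly. The selected, mode-weighted menu is therefore collapsed into
aggregate terms — encounter `Σ w_m·c_i·R_i`, encounter-weighted mean gut
factor and assimilation efficiency — and the single-prey solver runs on
the aggregates. For a *fixed* diet this collapse is exact, because all
prey share one feeding level; realized ingestion then distributes over
prey in proportion to their assimilated-encounter contribution, so
per-prey rates sum to the behavioral solution's `g` identically. What
remains approximate is the decision sequence itself: the diet chosen at
`f_feed = 1` is not re-optimized at `p*`.

## The food-web simulator

Seven pools in a single conserved mass currency (nutrient-equivalent
biomass, g m⁻³, all column-averaged; benthic pools are treated
volumetrically, so in a 0-D column the water-column averaging of a layered
model is the identity): dissolved nutrient, phytoplankton, zooplankton,
zoobenthos, sediment POM, omnivorous fish, predator fish. A single
currency replaces multi-element stoichiometry deliberately: the questions
addressed here concern trophic dynamics, not nutrient ratios.

The lower-web closure is conventional and module-owned: Monod nutrient
uptake scaled by light and temperature for phytoplankton, Holling type II
grazing for zooplankton (on phytoplankton) and zoobenthos (on sediment
POM), linear respiration (to nutrient) and mortality (to POM), first-order
mineralization of POM back to nutrient. Fish feed through the multi-prey
machinery above; the omnivore's menu is zooplankton (pelagic mode),
zoobenthos and sediment POM (benthic mode, POM with a high gut factor of
4 reflecting low digestibility), the predator's menu is the omnivore
(piscivorous mode). Unassimilated ingestion and all mortality route to
POM; respiration routes to dissolved nutrient; the external nutrient load
is the only input and a small flush on the dissolved and phytoplankton
pools the only output. All temperature dependence is exponential Q10
scaling, `rate(T) = rate_ref·Q10^((T−20)/10)`, with Q10 defaults near 2.

The fraction `p*·f_PM` of omnivore biomass is unavailable to the predator;
the risk the omnivores perceive is the smoothed per-capita capture rate of
the predator population (`f_feed·c·(1 − F)·B_pred`), so predator behavior
feeds back on prey risk, and the realized predation flux equals the
predator's capture exactly — no double counting. The predator is the top
of the food chain: it experiences `m_pred.s = 0` and its behavioral
problem reduces to optimizing net energy gain; its `f_PM`/`f_FC` are
accepted in configuration but cannot affect any mortality. The control
("no behavior") model fixes `p = 0`, `f_feed = 1` for both groups, which
makes its trajectories independent of `f_PM` and `f_FC`; `f_RF` still
enters the control's metabolism (at full feeding activity), as the cost of
feeding is physiology, not behavior.

### Numerics

Forward Euler at `dt = 1` d, matching the daily cadence of the behavioral
decision and the risk smoother — the behavior is a per-step discrete
decision, not a smooth ODE term. Every transfer posts the same mass as a
loss on its source and a gain on its destination, so the scheme conserves
by construction; a ten-year closed run (zero load, zero flush) drifts by
~5e-15 relative. When a step would overdraw a pool, all of that pool's
outflows are scaled by a common factor so it lands exactly at zero (the
matched gains are reduced proportionally), and a floor of 1e-12 g m⁻³
keeps once-positive pools revivable; both corrections are ledgered so the
conservation accounting stays exact. Pools that start at exactly zero stay
at zero. Non-finite states abort with a diagnostic.

## Synthetic forcing

A strictly periodic 365-day year (no leap days): independent sinusoids for
water temperature (default 11 ± 9 °C, floored at 0, peaking late July),
light factor (0.5 ± 0.45, clamped to [0, 1], peaking at the solstice), and
nutrient load (0.02 ± 0.01 g m⁻³ d⁻¹, peaking in late winter/spring —
eutrophic-lake scale for the toy volume). Looping an identical year
excludes interannual environmental variability, so any between-year
variance in model output is endogenous. The load channel is multiplied by
`load_scale ∈ {0.25, 0.5, 1, 2, 4}` for the enrichment ladder. What this
forcing does *not* emulate: weather stochasticity, storm events,
stratification and mixing dynamics — so passing tests demonstrate the
behavioral mechanism under idealized seasonality, not predictive skill for
any real lake.

## Diagnostics

Stability is decomposed into a within-year CV (population sd over the
365-day mean climatology, divided by its mean — the 365 climatology days
are a complete population, hence the `n` denominator) and a between-year
CV (sample sd over annual means, `n − 1` denominator). Seasonal metrics
use fixed windows of the 365-day calendar: August is days 213–243, summer
(1 May–1 Oct) is days 121–274. The chlorophyll proxy is phytoplankton
biomass times a configurable conversion (default 10 proxy units per
g m⁻³); ratio metrics (predator fraction, zooplankton:phytoplankton) are
ratios of window means, which prevents days on which the denominator pool
washes out from dominating a mean of daily ratios.

## Protocols and problem sizes

Scenario runs loop the annual cycle for 100 model years and analyze the
last 50 (both configurable), discarding spin-up. The nutrient-loading
ladder uses 60-year runs (last 30 analyzed) per scale and configuration —
long enough that the analysis window statistics are insensitive to the
remaining transient at these turnover rates. The packaged cycling
calibration (`configs/cycling.yaml`) was selected by a deterministic grid
search over predator clearance and mortality (`make_cycling_fixture`): its
control run must show a multiyear fish cycle — between-year CV of
omnivorous fish above the declared floor of 0.2 — without either fish
group washing out, and switching behavior on (maximal trade-off) must
lower the between-year CV of both fish groups. On the frozen calibration
the control cycles with a ~4–5-year period (CV ≈ 0.42) and the behavioral
run damps it to ≈ 0.035. The loading scenarios use an omnivore trade-off
of `f_PM = 0.9`, `f_FC = 0.675` — efficient, intermediate-cost mitigation,
which partly releases the omnivore from top-down control and lets the
chlorophyll response to enrichment steepen relative to the control.

## Known limitations

* Monomorphic optimality: the whole population shares one `p*` each step;
  no game-theoretic equilibrium among individually optimizing fish, no
  energy-storage or condition state, no life stages.
* The diet/mode/effort decision order is fixed; diets are not re-optimized
  at the chosen effort level.
* 0-D: no vertical structure, oxygen, ice, macrophyte dynamics
  (`f_veg` is accepted as a supplied factor only) or hydrodynamics; the
  single-currency lower web is a closure, not a calibrated ecosystem
  model, and no numerical equivalence to any host-model parameterization
  is claimed.
* Forward Euler at a daily step ties process rates to the decision
  cadence; rates ≫ 0.5 d⁻¹ would need a finer step than the overdraw
  guard can gracefully absorb.
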