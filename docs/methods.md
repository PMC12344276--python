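# Methods

`chirosim` is an individual-based population model of the non-biting midge
*Chironomus riparius* in closed laboratory vessels, built around a Dynamic
Energy Budget (DEB) description of each larva, with two population-level
interactions: exploitative competition through a shared, depletable food
pool, and direct interference competition expressed as density-dependent
mortality. This note documents the model equations, the numerical scheme,
the shipped parameter set and the design decisions that were genuinely
open.

## Individual physiology

Each individual carries structural volume `V` [cm³], reserve energy `E`
[J], maturity `E_H` [J] and a reproduction buffer `E_R` [J]. The dynamics
are the standard DEB κ-rule with metabolic acceleration between birth and
puberty (the insect-type "accelerated" DEB family for holometabolans, with
explicit pupation and emergence on top):

    p_C = [E] (E_G v́ s_M V^(2/3) + [p_M] V) / (E_G + κ [E]),   [E] = E/V
    dE/dt  = p_A − p_C
    dV/dt  = max(0, κ p_C − [p_M] V) / E_G          (structure never shrinks)
    dE_H/dt = (1−κ) p_C − k_J E_H                   while E_H < E_H^p
    dE_R/dt = (1−κ) p_C − k_J E_H^p                 afterwards

Assimilation is `p_A = κ_X · ingestion`, with ingestion proportional to
surface area and accelerated: `z ṗ_Am s_M V^(2/3) f / κ_X` per day, where
`f` is the Holling type-II functional response of the local food density
and `z` an individual lognormal multiplier (see *Stochasticity*). The
acceleration factor `s_M = L/L_b` tracks structural length relative to
birth length and freezes at puberty (`E_H = E_H^p`); both the assimilation
rate and the conductance carry `s_M`, so the maximum reserve density
`[E_m] = z ṗ_Am / v́` is independent of `s_M` and the scaled reserve
density

    e = E v́ / (V z ṗ_Am)

equilibrates exactly to `f` at constant food — a property the test suite
verifies against a fine-step integration.

**Embryo.** Newborns are produced directly at the birth transition by
integrating the embryo (no feeding) with `e` held at 1 — development
without energy constraint — from near-zero structure until `E_H = E_H^b`.
This fixes the birth length `L_b` and the birth reserve consistently with
the rest of the parameter set.

**Pupation and emergence.** A larva pupates when its reproduction buffer
reaches the threshold `E_R^pup`; the pupa neither feeds nor grows and
emerges after a fixed `t_pupa` days. Whether the original implementations
of this model family trigger pupation on the buffer, on maturity or on
size is not documented publicly; the buffer threshold was chosen because
it gives one interpretable knob for the pupation size and one for clutch
energy, and it is isolated behind `advance_stage` for replacement.

**Metamorphosis energetics.** During the pupal stage reserve continues to
be mobilised at the κ-rule rate: the somatic branch covers maintenance
(the surplus is metamorphosis overhead), and the (1−κ) branch keeps
flowing into the reproduction buffer. Emerging females therefore convert
their remaining larval stores into eggs, `n = ⌊κ_R E_R / E_0⌋`. This is
what makes clutch size increase with food, as observed; freezing the
buffer during metamorphosis (the obvious alternative) pins the clutch to
the pupation threshold and erases the food–fecundity relationship.

**Starvation.** Reserve decay is exponential-like and never literally
reaches zero, so "complete depletion" is operationalised as death when
`e < e_starv` (default 0.01). No structure shrinking is modelled; a
maintenance shortfall simply accelerates reserve drain until the
threshold is crossed.

## Habitat and feeding

The habitat is a rectangular grid (default 20 cells × 0.025 m² = 0.5 m²,
arranged 4 × 5) whose cells carry a food energy density `X` [J m⁻²]. Each
day the experimental ration is added uniformly:

    ΔX = initial density [larvae m⁻²] × ration [mg larva⁻¹ d⁻¹] × F_C [J mg⁻¹]

using the *initial* density (the experiments fed by initial numbers), so
per-capita food rises as larvae die. Food accumulates without degradation
— losses to microbial decay and sediment mixing are folded into the
calibrated conversion factor `F_C`. Ingestion is computed hourly: each
larva's demand is evaluated at `f = X/(K_S + X)` of its cell at the start
of the hour; if the cell pool (`X ×` cell area) cannot cover the total
demand, it is divided in proportion to the individual demands
(simultaneous, order-independent). Mass balance of the pool holds to
1 × 10⁻⁹ relative over any horizon.

Vessels smaller than the default grid can be simulated in two modes:
*density scaling* (default) maps the vessel's areal density onto the grid
(a 50 cm² beaker with 20 larvae becomes 2000 individuals at 4000 m⁻²),
preserving all per-area quantities; *literal area* resizes the grid to
the vessel (a beaker becomes a single well-mixed cell). The modes agree
closely at equal density once populations are large enough; at very small
counts on many cells, random occupancy heterogeneity genuinely slows
development, which is why like must be compared with like in calibration
(see below).

## Population processes

**Density-dependent mortality.** A daily rate `y = a x^0.4` [% d⁻¹] in
the *global* larval density `x` (living larvae over total area); each
larva independently draws a fresh uniform number and dies when it falls
below `y/100`. Only larvae are at risk. The coefficient `a` can be
expressed per 50 cm² or per m² (`0.29` per 50 cm² ↔ `0.035` per m²,
conversion by `200^0.4`).

**Stochasticity.** Each individual receives, once at birth, a lognormal
multiplier `z = exp(N(0, σ))` on its maximum assimilation rate
(σ = 0.35, median 1, interpreted on the log scale). This is the dominant
source of the sigmoid spread of emergence curves; the random initial
placement and movement contribute a little more. Scenario results are
reported as means ± SD of 20 Monte-Carlo runs by default.

**Movement.** Once a day a larva stays in its cell with probability
`p_stay = clamp(e, 0, 1)` and otherwise steps to a uniformly chosen von
Neumann neighbour (edge cells have fewer candidates; no wrap — vessels
are closed). Only the monotonicity of movement in hunger is empirically
supported; the identity map is the simplest monotone choice and is
isolated in one function.

## Daily schedule and numerics

Per day, in fixed order: (1) food addition; (2) 24 hourly feeding rounds;
(3) DEB step for larvae with the day's accumulated assimilation, pupal
dynamics; (4) transitions (pupation, emergence; in closed populations
oviposition and hatching after a 3-day egg stage); (5) starvation check;
(6) density mortality at the current global density; (7) movement.
Mortality runs after growth, so an individual emerging on day *t* cannot
die on day *t*. The order is exposed only through this documentation; the
observable endpoints are insensitive to reasonable permutations at the
daily resolution.

The DEB state is advanced by explicit Euler. A single daily step is
unstable for small larvae (the reserve turnover rate `v́ s_M / L ≈ v́/L_b`
is ~9 d⁻¹ for the shipped set), so the daily step is subdivided into 24
explicit substeps with the day's assimilation spread evenly; the hourly
feeding demands themselves are evaluated at start-of-day size, matching
the hourly-uptake/daily-growth split of the scheme. One consequence worth
knowing: during the fast acceleration phase, `e` sits below the
instantaneous `f` because intake lags the within-day growth of the
assimilating surface; the equilibrium `e = f` is recovered exactly as the
step size shrinks, which is how the invariant is tested.

Determinism: one `numpy` Generator per run, seeded explicitly; identical
seeds give bitwise-identical output. Monte-Carlo runs use seeds spawned
from the base seed.

## Shipped DEB parameter set

The species parameters of the underlying DEB model for *C. riparius* are
not printed in the primary literature this package accompanies; the
package therefore ships one internally consistent default set (exposed in
`chirosim.DEFAULT_PARAMS`, exportable with `chirosim params`), tuned so
that the simulated life history at 20 °C is in the range reported for
laboratory cultures: emergence from about day 13 under food-unlimited
conditions, spreading over >1 week with σ = 0.35, clutches of several
hundred eggs increasing with food, and no starvation mortality at the
standard test rations (0.05–0.5 mg larva⁻¹ d⁻¹). Every constant is
replaceable through a flat key-value parameter file whose reader enforces
the invariants (0 < κ < 1, E_H^b < E_H^p, etc.). Quantities that depend
on the original calibrated parameter values are treated as conditional
throughout the package: the corresponding tests run only when a user
supplies a parameter file and observation data.

The energy scale of the set deserves a note. DEB dynamics are invariant
under a joint rescaling of every energy-dimensioned constant
(ṗ_Am, [p_M], E_G, E_H^b, E_H^p, E_R^pup, E_0): the life-history timing,
lengths, e-trajectories and clutch sizes are all unchanged. That free
scale was anchored so that, through a food conversion factor of
2.3 J mg⁻¹, the reference ration of 0.5 mg larva⁻¹ d⁻¹ is only mildly
limiting while the lower rations are progressively limiting and the
large-aquarium scenario (lowest areal food density relative to K_S) is
clearly slowed — the qualitative regime the experiments operate in. Any
residual offset between the model's ingestion scale and the true
calorimetric content of the food is, by construction, absorbed by the
calibrated `F_C`.

## Endpoints

Applied identically to observed and simulated series:

* total mortality `100 (N₀ − emerged − survivors)/N₀` [%] and the mean
  daily rate (total mortality / duration);
* cumulative emergence of surviving individuals,
  `100 · emerged(t) / (N₀ − dead at end)` [%], which excludes mortality
  from the development comparison;
* EmT₅₀ and slope `b` of the two-parameter log-logistic (Hill) curve
  `y = 1/(1 + (EmT₅₀/x)^b)`, fitted by maximising the binomial likelihood
  of the per-interval emergence increments (plus the never-emerged
  remainder), in log-parameter space with Nelder–Mead. `y(EmT₅₀) = 0.5`
  holds by construction; a least-squares fit on the cumulative curve is
  the fallback for degenerate (all-at-once) data. Whether the original
  replicate fits weighted days by the number still at risk is not
  documented; the increment-likelihood choice is isolated and stated.
* the density–mortality power law, fitted by ordinary least squares in
  log–log space, optionally with the exponent fixed at 0.4.

## Calibration

The three population-level constants — `K_S` [J m⁻²], `a` and `F_C`
[J mg⁻¹] — are estimated simultaneously by Nelder–Mead in log-parameter
space, minimising

    J(θ) = Σ_scenarios w_s Σ_days (sim. mean cumulative emergence fraction
                                   − observed replicate mean)²

The 200-larvae treatments are excluded (computing cost, and the
highest-food one is oxygen-confounded); the lowest-areal-density 600 cm²
aquarium scenario is weighted 8× because it alone pins down `K_S`. The
loss (SSE on fractions at observed days) is a documented choice — the
original loss is not public — and is swappable.

Objective evaluations use a small fixed number of Monte-Carlo runs with
common random numbers across θ, making the objective quasi-deterministic
so the simplex behaves as the deterministic optimiser it is. Simulations
inside the objective use the density-scaling protocol on a reduced
20-cell grid (default 0.1 m²): per-area dynamics are preserved while
counts stay in the thousands for the beakers. Low-density scenarios get
a proportionally larger grid so that at least ~400 individuals are
simulated — the aquarium mapped onto 0.1 m² would hold only 33, and its
Monte-Carlo error, amplified by the 8× weight, would otherwise dominate
the objective and the estimates. Two Nelder–Mead details matter on this
quasi-deterministic but rugged surface: the initial simplex is built wide
(log-space steps of 0.35) so vertices straddle flat regions (parameter
corners where no simulated emergence falls inside the observation
window), and after the first convergence the simplex is restarted at the
found point with 3× smaller steps — the classic guard against premature
collapse. Multi-restart with a dispersion report is also available.

**Parameter recovery.** The harness generates pseudo-observations from
the simulator itself at a known triple (default: `K_S = 1045 J m⁻²`,
`a = 0.29` per (larvae/50 cm²)^0.4, `F_C = 2.3 J mg⁻¹`), converts the
mean emergence profile into four replicate counts per scenario by
multinomial sampling over emergence days (monotone cumulative counts with
binomial marginals, matching the four-replicate design), and calibrates
against them with seeds disjoint from those of the generation step.
Under four-replicate noise a single calibration's estimate of `a`
scatters with an SD of roughly 0.02–0.03; the harness therefore follows
the protocol of repeated independent calibration runs — several
realisations, each calibrated once from a fresh dispersed start — and
reports the across-run mean, which recovers `a` to within ±0.02 (the
across-run SD doubles as the calibration dispersion). The recovery
scenario set spans three food levels, three densities (preferring the
100-larvae treatments, whose four replicates carry the least binomial
noise) and the aquarium that anchors `K_S`.

## What the synthetic data do and do not show

Pseudo-observations share the simulator's own structure, so recovery
demonstrates identifiability of (K_S, a, F_C) from emergence curves under
realistic replicate noise — not that the model is correct for real
midges. Real data add model error (instar structure, sediment chemistry,
sex differences, temperature fluctuation), replicate-level environmental
variation exceeding binomial noise, and outlier replicates; none of these
are emulated. Calibration against the real curves additionally requires
the original DEB parameter values, which this package does not ship.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full two-factorial
design as single seeded runs (density-scaled, 10³–2×10⁴ individuals per
scenario) for pattern checks, and the parameter recovery on five
scenarios (0.5, 0.25 and 0.125 mg larva⁻¹ d⁻¹ beakers at 40–100 larvae
plus the 600 cm² aquarium) with 4 pseudo-replicates, 2 Monte-Carlo runs
per objective evaluation on the 0.1 m² calibration grid, a 70-iteration
simplex budget per stage and 4 independent runs averaged. These sizes were
chosen as the smallest at which the Monte-Carlo noise of the objective is
clearly below the parameter tolerances being verified.

## Known limitations

* Constant 20 °C only; no Arrhenius temperature correction.
* Unsexed individuals; sex enters only as a fair coin at emergence in
  closed populations.
* No instar structure, no size-dependent attack rates in the mortality
  law, no cannibal–victim pairing — interference is a rate, not a
  mechanism.
* No food degradation or burial dynamics beyond what `F_C` absorbs.
* The pupation trigger and the movement probability are pragmatic,
  documented choices, each isolated behind a single function.
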