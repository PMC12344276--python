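# chirosim

An individual-based population model of the non-biting midge
*Chironomus riparius* in laboratory test vessels, for ecotoxicologists and
population modellers who need to separate **food limitation** from
**density-dependent mortality** in chironomid test systems.

Every larva is simulated with a Dynamic Energy Budget (DEB) model of the
accelerated, holometabolous type: assimilation `p_A = κ_X ż ṗ_Am s_M V^{2/3} f`
feeds a reserve that is mobilised by the κ-rule,

    p_C = [E] (E_G v̇ s_M V^{2/3} + [p_M] V) / (E_G + κ [E]),

with κ·p_C to maintenance and growth, (1−κ)·p_C to maturation and, after
puberty, to a reproduction buffer that triggers pupation and pays for the
clutch. Two population-level couplings close the model:

* **exploitative competition** — food on the sediment surface is an
  explicit, depletable pool `X` [J m⁻²]; uptake follows a Holling type-II
  functional response `f = X/(K_S + X)` with hourly depletion and
  proportional rationing when a cell runs short;
* **interference competition** — a daily mortality rate
  `y = a·x^{0.4}` [% d⁻¹] in the global larval density `x`, applied as an
  independent Bernoulli trial per larva.

The three population-level constants — `K_S` (half-saturation, J m⁻²),
`a` (mortality coefficient) and `F_C` (food conversion factor, J mg⁻¹) —
are calibrated against cumulative-emergence curves by Nelder–Mead simplex
in log space, and the package ships the standard chironomid test
endpoints (total mortality, daily mortality rate, and EmT₅₀ from a
two-parameter log-logistic fit by binomial maximum likelihood).

See `docs/methods.md` for model equations, parameter semantics, numerical
choices and limitations.

## Worked example

Simulate a standard OECD-style beaker (20 first-instar larvae on 50 cm²,
0.5 mg food larva⁻¹ d⁻¹) with the shipped DEB parameter set and the
calibrated population triple, then compute its endpoints:

```python
import chirosim as cs

scen = cs.Scenario(name="oecd_beaker", vessel_area_cm2=50, n_initial=20,
                   ration_mg=0.5, duration_d=None, stop_no_emergence_d=7)
pop = cs.PopulationParams(KS=1045.0, a=0.29, FC=2.3)

agg = cs.run_monte_carlo(scen, cs.DEFAULT_PARAMS, pop,
                         n_runs=20, base_seed=1)
f = agg.frame
n = agg.n_simulated
emerged = f["cum_emerged"].iloc[-1]
dead = (f["cum_dead_density"] + f["cum_dead_starvation"]).iloc[-1]
print(f"simulated individuals : {n}")
print(f"emerged by day {int(f['day'].iloc[-1])}    : "
      f"{100 * emerged / n:.1f} %")
print(f"mortality at test end : {100 * dead / n:.1f} %  "
      f"(starvation: {f['cum_dead_starvation'].iloc[-1]:.0f})")

pct = 100 * f["cum_emerged"] / (n - dead)
emt50, b, info = cs.fit_emt50(f["day"], pct, n - dead)
print(f"EmT50 = {emt50:.1f} d  (slope b = {b:.1f}, R2 = {info['R2']:.3f})")
```

Output:

```
simulated individuals : 2000
emerged by day 36    : 90.2 %
mortality at test end : 9.8 %  (starvation: 0)
EmT50 = 13.9 d  (slope b = 9.1, R2 = 1.000)
```

Reading: the 20-larvae beaker is density-scaled onto the model's 0.5 m²
grid (2000 individuals at the same 4000 m⁻² density), ~10 % of larvae die
from density-dependent interference (none starve at this ration), and
half of the surviving cohort has emerged by day ~14; the sigmoid spread
of the emergence curve comes from the log-normal individual variability
of the assimilation rate (σ = 0.35).

The same can be run from the shell:

```sh
chirosim params --out deb_params.txt          # export the default DEB set
chirosim simulate --scenario scenarios.yaml --pop-params pop.yaml \
                  --runs 20 --seed 1 --out results/
chirosim endpoints --curves observed.csv --out endpoints.csv
chirosim recover --seed 1                     # parameter-recovery harness
```

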