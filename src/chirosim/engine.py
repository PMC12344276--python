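"""Scheduler and Monte-Carlo runner.

Wires the physiological core, the food grid and the population processes
into the daily/hourly cycle and produces tidy per-day output.

Daily schedule (fixed order)
----------------------------
1. add the day's food ration to every cell;
2. 24 hourly feeding rounds (Holling type-II demand, proportional
   rationing within each cell, food depletion);
3. physiology: one daily DEB step per larva with the day's accumulated
   assimilation; pupal metamorphosis dynamics;
4. stage transitions: pupation, emergence (and, in closed populations,
   oviposition and egg hatching);
5. starvation check;
6. density-dependent mortality at the current global larval density;
7. movement.

Mortality runs after growth and transitions, so an individual emerging on
day t cannot die on day t.

The population is held as structure-of-arrays and every step uses the same
array kernels as the single-individual API in :mod:`chirosim.deb`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import deb as _deb
from .deb import DEBParams, DeathCause, Stage
from .habitat import (Habitat, PopulationParams, add_daily_food,
                      functional_response, hourly_feeding_round)
from .population import (apply_daily_mortality, density_mortality_rate,
                         move_individuals, neighbour_table,
                         population_density, sample_assimilation_factor)

__all__ = ["Scenario", "SimulationOutput", "run_scenario", "run_monte_carlo"]

CM2_PER_M2 = 1.0e4


@dataclass(frozen=True)
class Scenario:
    """One experimental design point.

    Attributes
    ----------
    name : scenario label.
    vessel_area_cm2 : sediment surface of the vessel [cm^2].
    n_initial : first-instar larvae introduced at test start.
    ration_mg : daily food [mg dw larva^-1 d^-1] (per-larva feeding mode).
    duration_d : fixed test duration [d]; None for open-ended scenarios
        terminated by the no-emergence stop rule.
    closed_population : if True, emerging adults stay, mate and oviposit
        (eggs hatch into new larvae after ``egg_lag_d``); if False adults
        are removed at emergence.
    feeding_mode : ``"per_larva"`` (ration scaled by the initial larval
        density) or ``"per_vessel"`` (a fixed daily mass per vessel,
        ``food_per_vessel_mg``, divided by the vessel area).
    food_per_vessel_mg : daily food mass per vessel [mg d^-1]
        (per-vessel mode only).
    density_scaling : if True (default) the scenario is mapped onto the
        default 0.5 m^2 grid preserving areal density; if False the grid
        is resized to the literal vessel area.
    grid_spec : optional (n_cells, cell_area [m^2]) override of the grid
        used for the run (literal-area mode only).
    stop_no_emergence_d : stop once this many consecutive days pass with
        no emergence after the first one (None disables the rule).
    max_duration_d : hard cap for open-ended runs.
    egg_lag_d : embryo duration between oviposition and hatching [d]
        (closed populations).
    tags : free-form labels (e.g. ``excluded_from_calibration``).
    """

    name: str
    vessel_area_cm2: float
    n_initial: int
    ration_mg: float
    duration_d: Optional[float] = None
    closed_population: bool = False
    feeding_mode: str = "per_larva"
    food_per_vessel_mg: float = 0.0
    density_scaling: bool = True
    grid_spec: Optional[tuple[int, float]] = None
    stop_no_emergence_d: Optional[float] = 7.0
    max_duration_d: float = 120.0
    egg_lag_d: float = 3.0
    tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.vessel_area_cm2 > 0:
            raise ValueError("vessel_area_cm2 must be > 0")
        if self.n_initial < 0:
            raise ValueError("n_initial must be >= 0")
        if self.ration_mg < 0:
            raise ValueError("ration_mg must be >= 0")
        if self.duration_d is not None and not self.duration_d > 0:
            raise ValueError("duration_d must be > 0")
        if self.duration_d is None and self.stop_no_emergence_d is None:
            raise ValueError("open-ended scenario needs a stop rule")
        if self.feeding_mode not in ("per_larva", "per_vessel"):
            raise ValueError("feeding_mode must be per_larva or per_vessel")
        if self.feeding_mode == "per_vessel" and self.food_per_vessel_mg < 0:
            raise ValueError("food_per_vessel_mg must be >= 0")
        if self.grid_spec is not None and not self.density_scaling:
            n_cells, cell_area = self.grid_spec
            if abs(n_cells * cell_area - self.vessel_area_m2) > 1e-12:
                raise ValueError(
                    "literal-area run: grid_spec area must equal the "
                    "vessel area")

    @property
    def vessel_area_m2(self) -> float:
        return self.vessel_area_cm2 / CM2_PER_M2

    @property
    def initial_density_per_m2(self) -> float:
        """Initial areal larval density [larvae m^-2]."""
        return self.n_initial / self.vessel_area_m2

    @property
    def per_capita_ration_mg(self) -> float:
        """Daily food per initial larva [mg larva^-1 d^-1] in either mode."""
        if self.feeding_mode == "per_larva":
            return self.ration_mg
        if self.n_initial == 0:
            return 0.0
        return self.food_per_vessel_mg / self.n_initial

    @property
    def daily_food_per_m2_mg(self) -> float:
        """Daily food mass per unit sediment area [mg m^-2 d^-1]."""
        if self.feeding_mode == "per_larva":
            return self.initial_density_per_m2 * self.ration_mg
        return self.food_per_vessel_mg / self.vessel_area_m2


@dataclass
class SimulationOutput:
    """Per-day ledger of one run (or a Monte-Carlo aggregate).

    ``frame`` has one row per day with stage counts, cumulative emergence,
    cumulative deaths by cause, the mean food density and mean scaled
    reserve density.  For aggregates, ``frame`` holds the across-run daily
    mean and ``frame_sd`` the daily standard deviation of cumulative
    emergence and deaths.
    """

    scenario: Scenario
    seed: Optional[int]
    n_simulated: int
    frame: pd.DataFrame
    deaths: Optional[pd.DataFrame] = None
    clutches: Optional[pd.DataFrame] = None
    frame_sd: Optional[pd.DataFrame] = None
    cell_frame: Optional[pd.DataFrame] = None
    n_runs: int = 1

    @property
    def final(self) -> pd.Series:
        return self.frame.iloc[-1]

    def cumulative_emergence_fraction(self) -> pd.Series:
        """Daily cumulative emerged / introduced larvae, indexed by day."""
        if self.n_simulated == 0:
            return pd.Series(0.0, index=self.frame["day"])
        s = self.frame.set_index("day")["cum_emerged"] / self.n_simulated
        return s


class _Population:
    """Structure-of-arrays state of every individual ever introduced."""

    def __init__(self) -> None:
        self.V = np.zeros(0)
        self.E = np.zeros(0)
        self.EH = np.zeros(0)
        self.ER = np.zeros(0)
        self.sM = np.zeros(0)
        self.Lb = np.zeros(0)
        self.z = np.zeros(0)
        self.cell = np.zeros(0, dtype=np.int64)
        self.stage = np.zeros(0, dtype=np.int8)
        self.age_in_stage = np.zeros(0)
        self.death_cause = np.zeros(0, dtype=np.int8)

    @property
    def n(self) -> int:
        return self.V.size

    def add_newborns(self, params: DEBParams, z: np.ndarray,
                     cells: np.ndarray) -> None:
        V, E, Lb = _init_embryo_arrays(params, z)
        n = z.size
        self.V = np.concatenate([self.V, V])
        self.E = np.concatenate([self.E, E])
        self.EH = np.concatenate([self.EH, np.full(n, params.EHb)])
        self.ER = np.concatenate([self.ER, np.zeros(n)])
        self.sM = np.concatenate([self.sM, np.ones(n)])
        self.Lb = np.concatenate([self.Lb, Lb])
        self.z = np.concatenate([self.z, z])
        self.cell = np.concatenate([self.cell, cells])
        self.stage = np.concatenate(
            [self.stage, np.full(n, Stage.LARVA, dtype=np.int8)])
        self.age_in_stage = np.concatenate([self.age_in_stage, np.zeros(n)])
        self.death_cause = np.concatenate(
            [self.death_cause, np.full(n, DeathCause.NONE, dtype=np.int8)])

    def e_scaled(self, params: DEBParams) -> np.ndarray:
        return _deb.scaled_reserve_density(self.E, self.V, self.z, self.sM,
                                           params)


def _integrate_embryos(params: DEBParams, z: np.ndarray, dt: float = 2.0e-3,
                       t_max: float = 200.0) -> np.ndarray:
    """Vectorised embryo integration (e held at 1, no feeding) until
    maturity reaches EHb; returns the birth structure V_b per embryo."""
    z = np.asarray(z, dtype=float)
    Em = z * params.pAm_median / params.v_dot
    V = np.full(z.shape, 1.0e-9)
    EH = np.zeros(z.shape)
    denom = params.EG_vol + params.kappa * Em
    t = 0.0
    active = EH < params.EHb
    while active.any():
        if t > t_max:
            raise RuntimeError("embryo integration did not reach EHb")
        pC = Em * (params.EG_vol * params.v_dot * V ** (2.0 / 3.0)
                   + params.pM_vol * V) / denom
        grow = np.maximum(0.0, params.kappa * pC - params.pM_vol * V)
        V = np.where(active, V + grow * dt / params.EG_vol, V)
        EH = np.where(active,
                      EH + ((1.0 - params.kappa) * pC - params.kJ * EH) * dt,
                      EH)
        active = EH < params.EHb
        t += dt
    return V


# birth structure varies smoothly (and only weakly) with the scatter
# multiplier z, so it is integrated once per parameter set on a log-z grid
# and interpolated for each newborn
_EMBRYO_CACHE: dict[DEBParams, tuple[np.ndarray, np.ndarray]] = {}
_LOG_Z_GRID = np.linspace(-2.5, 2.5, 81)


def _init_embryo_arrays(params: DEBParams, z: np.ndarray):
    """Birth state (V, E, Lb) for newborns with scatter multipliers z."""
    z = np.asarray(z, dtype=float)
    if params not in _EMBRYO_CACHE:
        _EMBRYO_CACHE[params] = (_LOG_Z_GRID,
                                 _integrate_embryos(params,
                                                    np.exp(_LOG_Z_GRID)))
    grid, Vb_grid = _EMBRYO_CACHE[params]
    logz = np.log(z)
    if logz.size and (logz.min() < grid[0] or logz.max() > grid[-1]):
        V = _integrate_embryos(params, z)  # outside the cached range
    else:
        V = np.interp(logz, grid, Vb_grid)
    Em = z * params.pAm_median / params.v_dot
    return V, V * Em, V ** (1.0 / 3.0)


def _resolve_grid(scenario: Scenario) -> Habitat:
    if scenario.grid_spec is not None:
        n_cells, cell_area = scenario.grid_spec
        shape = {1: (1, 1), 20: (4, 5)}.get(n_cells, (1, n_cells))
        return Habitat(n_cells=n_cells, cell_area=cell_area, shape=shape)
    if scenario.density_scaling:
        return Habitat()  # the default 20 x 0.025 m^2 = 0.5 m^2 grid
    return Habitat.for_area(scenario.vessel_area_m2)


def simulated_count(scenario: Scenario) -> int:
    """Number of individuals actually simulated for the scenario.

    In density-scaled mode the initial areal density is mapped onto the
    run grid (the default 0.5 m^2 map, or ``grid_spec`` if given); in
    literal-area mode the experimental count is used as is.
    """
    if not scenario.density_scaling:
        return scenario.n_initial
    grid_area = _resolve_grid(scenario).total_area
    return int(round(scenario.initial_density_per_m2 * grid_area))


def run_scenario(scenario: Scenario, deb_params: DEBParams,
                 pop: PopulationParams, seed: int,
                 record_cells: bool = False,
                 n_substeps: int = 24) -> SimulationOutput:
    """Execute one seeded run of a scenario; returns the daily ledger."""
    rng = np.random.default_rng(seed)
    habitat = _resolve_grid(scenario)
    neighbours = neighbour_table(habitat.shape)
    a_m2 = pop.a_per_m2

    n0 = simulated_count(scenario)
    popn = _Population()
    if n0 > 0:
        z0 = np.asarray(sample_assimilation_factor(
            deb_params.sigma_pAm, rng, size=n0))
        cells0 = rng.integers(0, habitat.n_cells, size=n0)
        popn.add_newborns(deb_params, z0, cells0)
    n_introduced = n0

    # feeding is defined by the initial density (per-larva mode) or the
    # per-area mass (per-vessel mode); both are preserved by density scaling
    daily_food_mg_m2 = scenario.daily_food_per_m2_mg

    pending_eggs: list[tuple[float, int]] = []  # (hatch day, count)
    death_log: list[tuple[int, int, int, int]] = []  # (day, cause, cell, id)
    clutch_log: list[tuple[int, int]] = []  # (day, eggs)
    rows = []
    cell_rows = []
    cum_emerged = 0
    cum_dead_density = 0
    cum_dead_starv = 0
    last_emergence_day: Optional[int] = None

    max_day = scenario.duration_d if scenario.duration_d is not None \
        else scenario.max_duration_d
    day = 0
    while day < max_day:
        day += 1
        # (1) food addition
        add_daily_food(habitat, 1.0, daily_food_mg_m2, pop.FC)

        larva = popn.stage == Stage.LARVA
        idx = np.nonzero(larva)[0]
        intake = np.zeros(idx.size)
        # (2) 24 hourly feeding rounds, all cells advanced simultaneously
        if idx.size:
            cells_of = popn.cell[idx]
            V23 = popn.V[idx] ** (2.0 / 3.0)
            cap = (popn.z[idx] * deb_params.pAm_median / deb_params.kappaX
                   * popn.sM[idx] * V23 / 24.0)
            X = habitat.X
            area = habitat.cell_area
            for _hour in range(24):
                f = X / (pop.KS + X)
                demand = cap * f[cells_of]
                dem_cell = np.bincount(cells_of, weights=demand,
                                       minlength=habitat.n_cells)
                avail = X * area
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratio = np.where(dem_cell > 0,
                                     np.minimum(1.0, avail / dem_cell), 0.0)
                ingested = demand * ratio[cells_of]
                eaten_cell = np.bincount(cells_of, weights=ingested,
                                         minlength=habitat.n_cells)
                X = np.maximum(0.0, X - eaten_cell / area)
                intake += deb_params.kappaX * ingested
            habitat.set_X(X)

        # (3) physiology: larvae, then pupae
        if idx.size:
            (popn.V[idx], popn.E[idx], popn.EH[idx], popn.ER[idx],
             popn.sM[idx], _) = _deb.deb_step_arrays(
                popn.V[idx], popn.E[idx], popn.EH[idx], popn.ER[idx],
                popn.sM[idx], popn.Lb[idx], intake, 1.0, deb_params,
                n_substeps)
            popn.age_in_stage[idx] += 1.0
        pup = np.nonzero(popn.stage == Stage.PUPA)[0]
        if pup.size:
            popn.E[pup], popn.ER[pup] = _deb.pupa_step_arrays(
                popn.E[pup], popn.V[pup], popn.ER[pup], popn.sM[pup],
                deb_params, 1.0)
            popn.age_in_stage[pup] += 1.0

        # (4) transitions: pupation, emergence, oviposition, hatching
        pupate = larva & (popn.ER >= deb_params.ER_pup)
        popn.stage[pupate] = Stage.PUPA
        popn.age_in_stage[pupate] = 0.0
        emerge = (popn.stage == Stage.PUPA) \
            & (popn.age_in_stage >= deb_params.t_pupa) & ~pupate
        n_emerge = int(emerge.sum())
        if n_emerge:
            popn.stage[emerge] = Stage.ADULT
            popn.age_in_stage[emerge] = 0.0
            cum_emerged += n_emerge
            last_emergence_day = day
            if not scenario.closed_population:
                # open population: adults are removed; record the clutch
                # each would produce (fecundity-at-emergence diagnostic)
                for i in np.nonzero(emerge)[0]:
                    clutch_log.append((day, int(math.floor(
                        deb_params.kappaR * popn.ER[i] / deb_params.E0))))
            if scenario.closed_population:
                female = rng.uniform(size=n_emerge) < 0.5
                for i, fem in zip(np.nonzero(emerge)[0], female):
                    if fem:
                        eggs = int(math.floor(
                            deb_params.kappaR * popn.ER[i] / deb_params.E0))
                        popn.ER[i] -= eggs * deb_params.E0 / deb_params.kappaR
                        if eggs > 0:
                            clutch_log.append((day, eggs))
                            pending_eggs.append(
                                (day + scenario.egg_lag_d, eggs))
        if scenario.closed_population and pending_eggs:
            due = [pe for pe in pending_eggs if pe[0] <= day]
            if due:
                pending_eggs = [pe for pe in pending_eggs if pe[0] > day]
                n_new = sum(c for _, c in due)
                z_new = np.asarray(sample_assimilation_factor(
                    deb_params.sigma_pAm, rng, size=n_new))
                cells_new = rng.integers(0, habitat.n_cells, size=n_new)
                popn.add_newborns(deb_params, z_new, cells_new)
                n_introduced += n_new

        # (5) starvation
        larva = popn.stage == Stage.LARVA
        if larva.any():
            e_all = popn.e_scaled(deb_params)
            starved = larva & (e_all < deb_params.e_starv)
            n_starved = int(starved.sum())
            if n_starved:
                popn.stage[starved] = Stage.DEAD
                popn.death_cause[starved] = DeathCause.STARVATION
                cum_dead_starv += n_starved
                death_log.extend(
                    (day, int(DeathCause.STARVATION), int(popn.cell[i]),
                     int(i)) for i in np.nonzero(starved)[0])

        # (6) density-dependent mortality at the current global density
        larva_idx = np.nonzero(popn.stage == Stage.LARVA)[0]
        if larva_idx.size:
            x_m2 = population_density(larva_idx.size, habitat)
            rate = density_mortality_rate(x_m2, a_m2, pop.b_mort)
            dies = apply_daily_mortality(larva_idx.size, min(rate, 100.0),
                                         rng)
            victims = larva_idx[dies]
            if victims.size:
                popn.stage[victims] = Stage.DEAD
                popn.death_cause[victims] = DeathCause.DENSITY
                cum_dead_density += victims.size
                death_log.extend((day, int(DeathCause.DENSITY),
                                  int(popn.cell[i]), int(i))
                                 for i in victims)

        # (7) movement
        larva_idx = np.nonzero(popn.stage == Stage.LARVA)[0]
        if larva_idx.size and habitat.n_cells > 1:
            e_l = _deb.scaled_reserve_density(
                popn.E[larva_idx], popn.V[larva_idx], popn.z[larva_idx],
                popn.sM[larva_idx], deb_params)
            popn.cell[larva_idx] = move_individuals(
                popn.cell[larva_idx], e_l, neighbours, rng)

        n_larvae = int((popn.stage == Stage.LARVA).sum())
        n_pupae = int((popn.stage == Stage.PUPA).sum())
        n_adults_resident = int((popn.stage == Stage.ADULT).sum()) \
            if scenario.closed_population else 0
        mean_e = float(np.mean(popn.e_scaled(deb_params)[popn.stage ==
                                                         Stage.LARVA])) \
            if n_larvae else np.nan
        rows.append({
            "day": day,
            "n_larvae": n_larvae,
            "n_pupae": n_pupae,
            "n_adults": n_adults_resident,
            "n_eggs_pending": int(sum(c for _, c in pending_eggs)),
            "cum_emerged": cum_emerged,
            "cum_dead_density": cum_dead_density,
            "cum_dead_starvation": cum_dead_starv,
            "mean_X": float(habitat.X.mean()),
            "mean_e": mean_e,
        })
        if record_cells:
            for c in habitat.cells:
                cell_rows.append({"day": day, "cell": c.index, "X": c.X})

        if scenario.duration_d is None:
            if last_emergence_day is not None and \
                    day - last_emergence_day >= scenario.stop_no_emergence_d:
                break
            alive = n_larvae + n_pupae + len(pending_eggs)
            if alive == 0 and n_introduced > 0:
                break

    frame = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["day", "n_larvae", "n_pupae", "n_adults", "n_eggs_pending",
                 "cum_emerged", "cum_dead_density", "cum_dead_starvation",
                 "mean_X", "mean_e"])
    deaths = pd.DataFrame(death_log,
                          columns=["day", "cause", "cell", "id"])
    clutches = pd.DataFrame(clutch_log, columns=["day", "eggs"])
    return SimulationOutput(
        scenario=scenario, seed=seed, n_simulated=n0, frame=frame,
        deaths=deaths, clutches=clutches,
        cell_frame=pd.DataFrame(cell_rows) if record_cells else None)


def run_monte_carlo(scenario: Scenario, deb_params: DEBParams,
                    pop: PopulationParams, n_runs: int = 20,
                    base_seed: int = 0,
                    n_substeps: int = 24) -> SimulationOutput:
    """Aggregate ``n_runs`` independent seeded runs of one scenario.

    Runs use seeds spawned deterministically from ``base_seed``.  The
    aggregate frame carries the across-run daily mean of all counts
    (cumulative series are forward-filled past each run's stop day) and
    ``frame_sd`` the daily SD of the cumulative emergence/death columns.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = np.random.SeedSequence(base_seed).generate_state(n_runs)
    runs = [run_scenario(scenario, deb_params, pop, int(s),
                         n_substeps=n_substeps) for s in seeds]
    horizon = max(len(r.frame) for r in runs)
    cols = ["n_larvae", "n_pupae", "n_adults", "n_eggs_pending",
            "cum_emerged", "cum_dead_density", "cum_dead_starvation",
            "mean_X", "mean_e"]
    stacks = {c: [] for c in cols}
    for r in runs:
        fr = r.frame
        for c in cols:
            v = fr[c].to_numpy(dtype=float)
            if v.size < horizon:  # cumulative columns stay flat after stop
                pad_val = v[-1] if v.size else 0.0
                v = np.concatenate([v, np.full(horizon - v.size, pad_val)])
            stacks[c].append(v)
    mean = pd.DataFrame({c: np.mean(stacks[c], axis=0) for c in cols})
    mean.insert(0, "day", np.arange(1, horizon + 1))
    sd = pd.DataFrame({c: np.std(stacks[c], axis=0, ddof=0)
                       for c in ("cum_emerged", "cum_dead_density",
                                 "cum_dead_starvation")})
    sd.insert(0, "day", np.arange(1, horizon + 1))
    clutches = pd.concat([r.clutches for r in runs], ignore_index=True) \
        if runs[0].clutches is not None else None
    return SimulationOutput(scenario=scenario, seed=base_seed,
                            n_simulated=runs[0].n_simulated, frame=mean,
                            frame_sd=sd, n_runs=n_runs, clutches=clutches)
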