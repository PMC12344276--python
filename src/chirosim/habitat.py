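"""Gridded sediment surface: food-energy bookkeeping and hourly uptake.

The habitat is a rectangular grid of cells, each carrying a food energy
density ``X`` [J m^-2] on the sediment surface.  Food is added once a day
(the experimental ration converted to energy through the food conversion
factor F_C), accumulates without degradation, and is removed only by larval
ingestion.  Uptake follows a Holling type-II functional response
``f = X / (K_S + X)``; when the food in a cell cannot cover every larva's
potential intake within an hour, the available energy is split in
proportion to the individual demands.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import yaml

from .deb import DEBParams, potential_ingestion_arrays

__all__ = [
    "Cell",
    "Habitat",
    "PopulationParams",
    "functional_response",
    "daily_energy_addition",
    "add_daily_food",
    "hourly_feeding_round",
    "convert_mortality_coefficient",
    "B_MORT_DEFAULT",
]

#: Exponent of the density-mortality power law (see :mod:`chirosim.population`).
B_MORT_DEFAULT = 0.4

#: Area [m^2] of a standard 50 cm^2 test beaker, the density unit in which
#: the mortality coefficient is usually reported.
BEAKER_AREA_M2 = 0.005


@dataclass(frozen=True)
class PopulationParams:
    """Population-level parameters (the three calibrated constants).

    Attributes
    ----------
    KS : half-saturation constant of the feeding functional response [J m^-2].
    a : density-mortality coefficient [% d^-1 per (larvae per `a_density_unit`)^b].
    FC : food conversion factor [J per mg dw food].
    b_mort : mortality power-law exponent (fixed 0.4 unless overridden).
    a_density_unit : unit in which densities enter the power law for the
        given ``a``; one of ``"per_50cm2"`` or ``"per_m2"``.
    """

    KS: float
    a: float
    FC: float
    b_mort: float = B_MORT_DEFAULT
    a_density_unit: str = "per_50cm2"

    def __post_init__(self) -> None:
        if not self.KS > 0:
            raise ValueError("KS must be > 0")
        if self.a < 0:
            raise ValueError("a must be >= 0")
        if not self.FC > 0:
            raise ValueError("FC must be > 0")
        if self.a_density_unit not in ("per_50cm2", "per_m2"):
            raise ValueError("a_density_unit must be 'per_50cm2' or 'per_m2'")

    @property
    def a_per_m2(self) -> float:
        """The mortality coefficient expressed for densities in larvae m^-2."""
        if self.a_density_unit == "per_m2":
            return self.a
        return convert_mortality_coefficient(
            self.a, "per_50cm2", "per_m2", self.b_mort)


def load_population_params(path: Union[str, Path]) -> PopulationParams:
    """Read population-level parameters from a small YAML mapping."""
    data = yaml.safe_load(Path(path).read_text())
    allowed = {f.name for f in dataclasses.fields(PopulationParams)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown population parameters {sorted(unknown)}")
    return PopulationParams(**data)


def dump_population_params(params: PopulationParams,
                           path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(params),
                                         sort_keys=False))


def convert_mortality_coefficient(a: float, from_unit: str, to_unit: str,
                                  b_mort: float = B_MORT_DEFAULT) -> float:
    """Re-express the power-law coefficient for a different density unit.

    With y = a x^b and x measured per 50 cm^2, switching to x per m^2
    multiplies densities by 200, so the coefficient divides by 200^b.
    """
    scale = {"per_50cm2": BEAKER_AREA_M2, "per_m2": 1.0}
    try:
        ratio = scale[from_unit] / scale[to_unit]
    except KeyError as exc:
        raise ValueError(f"unknown density unit {exc}") from None
    return a * ratio ** b_mort


@dataclass
class Cell:
    """One grid cell with its surface food energy density."""

    index: int
    X: float = 0.0  # J m^-2

    def __post_init__(self) -> None:
        if self.X < 0:
            raise ValueError("food energy density X must be >= 0")


@dataclass
class Habitat:
    """The gridded sediment surface.

    The default grid is 20 cells of 0.025 m^2 (4 x 5), totalling 0.5 m^2.
    ``shape`` gives the (rows, cols) arrangement used for the von Neumann
    neighbourhoods of the movement module.
    """

    n_cells: int = 20
    cell_area: float = 0.025  # m^2
    shape: tuple[int, int] = (4, 5)
    cells: list[Cell] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.shape[0] * self.shape[1] != self.n_cells:
            raise ValueError("shape must tile exactly n_cells")
        if not self.cells:
            self.cells = [Cell(i) for i in range(self.n_cells)]
        elif len(self.cells) != self.n_cells:
            raise ValueError("cells length must equal n_cells")

    @property
    def total_area(self) -> float:
        """Total sediment area [m^2]."""
        return self.n_cells * self.cell_area

    @property
    def X(self) -> np.ndarray:
        """Food energy densities of all cells [J m^-2] as an array view."""
        return np.array([c.X for c in self.cells])

    def set_X(self, values) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_cells,):
            raise ValueError("values must have one entry per cell")
        if np.any(values < 0):
            raise ValueError("food energy density X must be >= 0")
        for cell, x in zip(self.cells, values):
            cell.X = float(x)

    def total_food_energy(self) -> float:
        """Total food energy on the surface [J]."""
        return float(self.X.sum() * self.cell_area)

    @classmethod
    def for_area(cls, area_m2: float, max_cell_area: float = 0.025
                 ) -> "Habitat":
        """Build a grid covering ``area_m2`` (literal-area mode).

        Uses a 4 x 5 arrangement of 20 equal cells whenever the vessel is
        large enough that a cell stays below ``max_cell_area``; small
        vessels (beakers) get a single cell — a 50 cm^2 beaker has no
        meaningful internal spatial structure.
        """
        if area_m2 <= 0:
            raise ValueError("area must be positive")
        if area_m2 / 20.0 >= 1.0e-3:
            return cls(n_cells=20, cell_area=area_m2 / 20.0, shape=(4, 5))
        return cls(n_cells=1, cell_area=area_m2, shape=(1, 1))


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------


def functional_response(X, KS: float):
    """Holling type-II functional response f = X / (KS + X) in [0, 1)."""
    if KS <= 0:
        raise ValueError("KS must be > 0")
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("food density X must be >= 0")
    out = X / (KS + X)
    return float(out) if out.ndim == 0 else out


def daily_energy_addition(initial_density_per_m2: float, ration_mg: float,
                          FC: float) -> float:
    """Daily food-energy addition [J m^-2 d^-1].

    The experimental feeding is defined by the *initial* larval density:
    addition = initial density [larvae m^-2] x ration [mg larva^-1 d^-1]
    x F_C [J mg^-1].
    """
    return initial_density_per_m2 * ration_mg * FC


def add_daily_food(habitat: Habitat, initial_density_per_m2: float,
                   ration_mg: float, FC: float) -> float:
    """Add the day's food uniformly to every cell; returns the J m^-2 added.

    Food never degrades; only ingestion removes it.
    """
    dX = daily_energy_addition(initial_density_per_m2, ration_mg, FC)
    for cell in habitat.cells:
        cell.X += dX
    return dX


def hourly_feeding_round(cell: Cell, cell_area: float, V, sM, z,
                         deb: DEBParams, KS: float):
    """One hourly uptake round in one cell (vectorised over its larvae).

    Demands are evaluated at the functional response of the cell's food
    density at the start of the hour.  If the cell holds enough energy
    (``X * cell_area``), every larva ingests its demand; otherwise the
    available energy is split proportionally to demand (simultaneous,
    order-independent).

    ``V``, ``sM``, ``z`` are arrays over the larvae currently in the cell.
    Returns ``(ingested, assimilated)`` arrays [J] aligned with the larvae
    (assimilated = kappaX * ingested) and decrements ``cell.X`` by the
    total ingestion per unit area.
    """
    V = np.asarray(V, dtype=float)
    if V.size == 0:
        return np.zeros(0), np.zeros(0)
    f = functional_response(cell.X, KS)
    demand = potential_ingestion_arrays(V, sM, z, f, deb)  # J h^-1
    total_demand = float(demand.sum())
    available = cell.X * cell_area  # J
    if total_demand <= available or total_demand == 0.0:
        ingested = demand
    else:
        ingested = demand * (available / total_demand)
    cell.X = max(0.0, cell.X - float(ingested.sum()) / cell_area)
    return ingested, deb.kappaX * ingested
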