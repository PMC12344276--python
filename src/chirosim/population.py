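"""Population-level processes.

Three mechanisms act on top of the individual physiology:

* density-dependent interference mortality — a power law
  ``y = a x^0.4`` [% d^-1] in the *global* larval density x (living larvae
  over total sediment area), applied as an independent daily Bernoulli
  trial per larva;
* inter-individual variability — a log-normal multiplier on the maximum
  assimilation rate, drawn once at birth;
* energy-state-dependent movement — a larva stays in its cell with
  probability equal to its scaled reserve density, otherwise it steps to a
  uniformly chosen von Neumann neighbour (no wrap-around: vessels are
  closed).
"""

from __future__ import annotations

import warnings

import numpy as np

from .habitat import B_MORT_DEFAULT, Habitat

__all__ = [
    "density_mortality_rate",
    "apply_daily_mortality",
    "population_density",
    "sample_assimilation_factor",
    "neighbour_table",
    "move_individuals",
]


def density_mortality_rate(x, a: float, b_mort: float = B_MORT_DEFAULT):
    """Daily interference-mortality rate y = a x^b [% d^-1].

    ``x`` is the larval density in the unit matching ``a`` (per 50 cm^2 or
    per m^2; see :class:`chirosim.habitat.PopulationParams`).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("larval density must be >= 0")
    out = a * x ** b_mort
    return float(out) if out.ndim == 0 else out


def apply_daily_mortality(n_larvae: int, rate_pct: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Daily Bernoulli mortality trial for each larva.

    Each larva draws a fresh uniform number u in (0, 1) and dies iff
    u < rate/100.  Applies to larvae only (the caller restricts the set).
    Returns a boolean array, True = dies today.  Rates above 100 % d^-1
    are clamped with a warning.
    """
    if rate_pct < 0:
        raise ValueError("mortality rate must be >= 0")
    if rate_pct > 100.0:
        warnings.warn(f"daily mortality rate {rate_pct:.3g} % d^-1 clamped "
                      "to 100", stacklevel=2)
        rate_pct = 100.0
    return rng.uniform(size=n_larvae) < rate_pct / 100.0


def population_density(n_living_larvae: int, habitat: Habitat) -> float:
    """Global larval density [larvae m^-2]: living larvae / total area."""
    return n_living_larvae / habitat.total_area


def sample_assimilation_factor(sigma: float, rng: np.random.Generator,
                               size=None):
    """Individual assimilation multiplier z = exp(N(0, sigma)).

    Log-normal with median 1; sigma is the standard deviation on the log
    scale.  Assigned once at birth and fixed for life.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return 1.0 if size is None else np.ones(size)
    draw = np.exp(rng.normal(0.0, sigma, size=size))
    return float(draw) if size is None else draw


def neighbour_table(shape: tuple[int, int]) -> list[np.ndarray]:
    """Von Neumann neighbour indices for every cell of a rows x cols grid.

    Cells are numbered row-major.  Edge and corner cells simply have fewer
    candidates (no wrap, no reflection).
    """
    rows, cols = shape
    table = []
    for r in range(rows):
        for c in range(cols):
            nb = []
            if r > 0:
                nb.append((r - 1) * cols + c)
            if r < rows - 1:
                nb.append((r + 1) * cols + c)
            if c > 0:
                nb.append(r * cols + c - 1)
            if c < cols - 1:
                nb.append(r * cols + c + 1)
            table.append(np.array(nb, dtype=np.int64))
    return table


def move_individuals(cell_idx: np.ndarray, e: np.ndarray,
                     neighbours: list[np.ndarray],
                     rng: np.random.Generator) -> np.ndarray:
    """Daily energy-dependent relocation of larvae on the grid.

    Each larva stays with probability p_stay = clamp(e, 0, 1); a mover
    relocates to a uniformly chosen existing von Neumann neighbour of its
    cell.  Returns the new cell index array.
    """
    cell_idx = np.asarray(cell_idx)
    if cell_idx.size == 0:
        return cell_idx.copy()
    p_stay = np.clip(np.asarray(e, dtype=float), 0.0, 1.0)
    u = rng.uniform(size=cell_idx.size)
    movers = np.nonzero(u > p_stay)[0]
    new_idx = cell_idx.copy()
    if movers.size:
        # draw a uniform slot among each mover's (<= 4) candidate neighbours
        counts_all = np.array([len(nb) for nb in neighbours])
        padded = np.zeros((len(neighbours), counts_all.max()),
                          dtype=np.int64)
        for i, nb in enumerate(neighbours):
            padded[i, :len(nb)] = nb
        from_cells = cell_idx[movers]
        slots = rng.integers(0, counts_all[from_cells])
        new_idx[movers] = padded[from_cells, slots]
    return new_idx
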