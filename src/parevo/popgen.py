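"""Population-parameter derivations from recombination and diversity.

Given a whole-region population-scaled recombination rate ρ = 4·Ne·r and a
fixed genetic length r (Morgans), the effective population size is
Ne = ρ / (4r). Combining with pairwise diversity π = 4·Ne·μ gives the
region-specific per-generation mutation rate μ = π·r/ρ, convertible to a
per-year rate with a generation time. A small accounting model attributes a
fraction of region mutations to the elevated de novo rate around the
obligate male crossover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import constants


@dataclass
class PopulationParams:
    population: str
    rho_total: float
    pi: float
    genetic_length: float      # Morgans
    generation_time: float     # years
    ne: int
    mu_pg: float               # per site per generation
    mu_py: float               # per site per year

    def to_series(self) -> pd.Series:
        return pd.Series(vars(self))


def effective_size(rho_total: float, genetic_length_morgans: float) -> int:
    """Ne = ρ / (4 r), rounded to the nearest individual for reporting."""
    if rho_total <= 0 or genetic_length_morgans <= 0:
        raise ValueError("inputs must be positive")
    return int(round(rho_total / (4.0 * genetic_length_morgans)))


def mutation_rate(pi: float, rho_total: float, genetic_length_morgans: float,
                  generation_time_years: float) -> tuple[float, float]:
    """(μ per generation, μ per year) from π/ρ = μ/r."""
    if min(pi, rho_total, genetic_length_morgans, generation_time_years) <= 0:
        raise ValueError("inputs must be positive")
    mu_pg = pi * genetic_length_morgans / rho_total
    return mu_pg, mu_pg / generation_time_years


def fold_vs_reference(rates, reference_rate: float) -> pd.Series:
    """Element-wise rate/reference folds with min, max and mean attributes."""
    if reference_rate <= 0:
        raise ValueError("reference rate must be positive")
    folds = pd.Series(np.asarray(rates, dtype=float) / reference_rate)
    folds.attrs.update(min=float(folds.min()), max=float(folds.max()),
                       mean=float(folds.mean()))
    return folds


def crossover_contribution(region_length_bp: float, crossover_window_bp: float,
                           local_rate: float, background_rate: float,
                           include_excess_in_denominator: bool = True) -> float:
    """Fraction of region mutations attributable to the obligate crossover.

    The crossover window (e.g. ±20 kb, i.e. 40 kb) mutates at `local_rate`
    instead of `background_rate`; the excess is divided by the total
    mutational input including the excess (or excluding it, if
    `include_excess_in_denominator` is False).
    """
    if crossover_window_bp > region_length_bp:
        raise ValueError("crossover window larger than the region")
    if local_rate < background_rate:
        raise ValueError("local rate below background")
    excess = crossover_window_bp * (local_rate - background_rate)
    base = region_length_bp * background_rate
    denom = base + excess if include_excess_in_denominator else base
    return excess / denom


def population_params_table(table: pd.DataFrame | None = None,
                            genetic_length: float | None = None,
                            ) -> pd.DataFrame:
    """Derive Ne and μ for every population in a (pop, rho, pi,
    generation_time) table; defaults to the bundled published table."""
    from .datasets import population_table

    if table is None:
        table = population_table()
    r = genetic_length if genetic_length is not None else \
        constants()["par1_genetic_length_morgans"]
    rows = []
    for rec in table.itertuples(index=False):
        if not np.isfinite(getattr(rec, "rho", np.nan)) or \
                not np.isfinite(getattr(rec, "generation_time", np.nan)):
            continue
        ne = effective_size(rec.rho, r)
        mu_pg, mu_py = mutation_rate(rec.pi, rec.rho, r, rec.generation_time)
        rows.append(PopulationParams(rec.pop, rec.rho, rec.pi, r,
                                     rec.generation_time, ne, mu_pg,
                                     mu_py).to_series())
    return pd.DataFrame(rows)
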