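"""Annual cradle-to-grave carbon accounting over a tree inventory.

Each simulated year, in order: trees age by one year and DBH is refreshed
from their growth curves; optionally a pruning fraction of above-ground
carbon is removed to the dead/residual pool (default off); then stratified
mortality moves each dying tree's full current-year carbon into the
accumulated dead pool.  No decomposition is modelled, so the dead pool only
grows.  Reports are emitted at the start year and every reporting interval,
per land-use class and in total: population, average age, alive and
accumulated-dead carbon (ktC) and their densities over the fixed land-cover
area (tC/ha), plus a high-uncertainty flag raised when the average age of
the population exceeds 80 years — an unlikely value for most urban trees.

In ``expected_value`` mortality mode the engine computes exact expectations:
with class survival ``w_c(t) = (1 - m_c)**t``, expected alive carbon is
``w_c(t) * sum_i carbon_i(t)`` and the expected dead-pool increment in year
``t`` is ``(w_c(t-1) - w_c(t)) * sum_i carbon_i(t)``; populations are then
continuous.  Stochastic mode draws individual Bernoulli deaths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allometry import (
    AllometryTable,
    DEFAULT_CARBON_FRACTION,
    biomass_from_dbh,
    mix_biomass_from_dbh,
)
from .growth import SpeciesRegistry, dbh_at_age, mix_curve
from .mortality import KG_PER_KT, MortalityModel

__all__ = ["LCAConfig", "run_lca", "carbon_density", "flag_average_age",
           "REPORT_COLUMNS"]

REPORT_COLUMNS = [
    "year", "land_use", "population", "average_age_years",
    "alive_ktC", "dead_ktC", "alive_tC_per_ha", "dead_tC_per_ha",
    "high_uncertainty_flag",
]


@dataclass
class LCAConfig:
    """Run configuration for the life-cycle simulation.

    ``land_cover_area_ha`` defaults to 70,000 ha (700 km2 of analysed land
    cover); densities divide all pools by this fixed area.  The horizon is
    preferably a multiple of the reporting interval; otherwise the final
    partial interval is still reported.
    """

    start_year: int = 2008
    horizon: int = 60
    report_interval: int = 10
    land_cover_area_ha: float = 70_000.0
    carbon_fraction: float = DEFAULT_CARBON_FRACTION
    avg_age_flag_threshold: float = 80.0
    pruning_enabled: bool = False
    pruning_fraction: float = 0.10
    pruning_interval: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.horizon < 1 or self.report_interval < 1:
            raise ValueError("horizon and report_interval must be >= 1")
        if self.land_cover_area_ha <= 0:
            raise ValueError("land_cover_area_ha must be > 0")
        if not 0 < self.carbon_fraction <= 1:
            raise ValueError("carbon_fraction must be in (0, 1]")
        if not 0 <= self.pruning_fraction < 1:
            raise ValueError("pruning_fraction must be in [0, 1)")

    @property
    def report_years(self) -> list[int]:
        years = list(range(0, self.horizon + 1, self.report_interval))
        if years[-1] != self.horizon:
            years.append(self.horizon)
        return [self.start_year + y for y in years]


def carbon_density(total_carbon_ktC: float, area_ha: float) -> float:
    """Carbon density in tC/ha from a pool in ktC over an area in hectares."""
    if area_ha <= 0:
        raise ValueError("area must be > 0")
    return total_carbon_ktC * 1000.0 / area_ha


def flag_average_age(average_age: float | None, threshold: float = 80.0) -> bool | None:
    """High-uncertainty flag: strictly greater than the threshold.

    ``None`` (empty population) propagates as ``None`` — the flag is
    undefined rather than false.
    """
    if average_age is None:
        return None
    return average_age > threshold


def _per_tree_carbon(dbh, species, registry, class_models, mix_models_mean_fn,
                     fraction):
    """Carbon (kg C) per tree given current DBH values and species labels."""
    carbon = np.empty(len(dbh))
    for cid in np.unique(species):
        mask = species == cid
        if registry[cid].family == "mix":
            carbon[mask] = fraction * mix_models_mean_fn(dbh[mask])
        else:
            carbon[mask] = fraction * biomass_from_dbh(class_models[cid], dbh[mask])
    return carbon


def run_lca(
    inventory: pd.DataFrame,
    registry: SpeciesRegistry,
    allometry: AllometryTable,
    mortality: MortalityModel,
    config: LCAConfig,
) -> pd.DataFrame:
    """Run the annual simulation; return the interval report series.

    The returned DataFrame has one row per report year and land-use class
    plus a ``"total"`` row (columns :data:`REPORT_COLUMNS`).  The input
    inventory is not modified.
    """
    # resolve every species/allometry key up front
    class_models = allometry.resolve_registry(registry)
    unknown = set(inventory["species_class"].astype(str)) - set(registry.class_ids)
    if unknown:
        raise ValueError(f"inventory species not in registry: {sorted(unknown)}")

    rng = np.random.default_rng(config.seed)
    mix = mix_curve(registry)

    n = len(inventory)
    species = inventory["species_class"].astype(str).to_numpy()
    land_use = inventory["land_use"].to_numpy()
    ages = inventory["age_years"].to_numpy(dtype=float).copy()
    dbh = inventory["dbh_cm"].to_numpy(dtype=float).copy()
    alive = inventory["alive"].to_numpy(dtype=bool).copy()

    expected = mortality.mode == "expected_value"
    uses = list(mortality.rates)
    use_masks = {u: land_use == u for u in uses}
    # class survival weights (expected-value mode)
    weights = {u: 1.0 for u in uses}
    dead_pool_kg = {u: 0.0 for u in uses}

    def mix_mean(d):
        return mix_biomass_from_dbh(allometry, registry, d)

    def carbon_now():
        out = np.zeros(n)
        if alive.any():
            out[alive] = _per_tree_carbon(
                dbh[alive], species[alive], registry, class_models, mix_mean,
                config.carbon_fraction)
        return out

    rows = []

    def emit(year: int, carbon_kg: np.ndarray) -> None:
        entries = []
        for u in uses:
            m = use_masks[u] & alive
            if expected:
                pop = float(m.sum()) * weights[u]
                avg_age = float(ages[m].mean()) if m.any() else None
                alive_kg = float(carbon_kg[m].sum()) * weights[u]
            else:
                pop = float(m.sum())
                avg_age = float(ages[m].mean()) if m.any() else None
                alive_kg = float(carbon_kg[m].sum())
            entries.append((u, pop, avg_age, alive_kg, dead_pool_kg[u]))
        total_pop = sum(e[1] for e in entries)
        if total_pop > 0:
            total_age = sum(e[1] * e[2] for e in entries if e[2] is not None) / total_pop
        else:
            total_age = None
        entries.append((
            "total", total_pop, total_age,
            sum(e[3] for e in entries), sum(e[4] for e in entries),
        ))
        for u, pop, avg_age, alive_kg, dead_kg in entries:
            alive_kt = alive_kg / KG_PER_KT
            dead_kt = dead_kg / KG_PER_KT
            rows.append({
                "year": year,
                "land_use": u,
                "population": pop,
                "average_age_years": avg_age,
                "alive_ktC": alive_kt,
                "dead_ktC": dead_kt,
                "alive_tC_per_ha": carbon_density(alive_kt, config.land_cover_area_ha),
                "dead_tC_per_ha": carbon_density(dead_kt, config.land_cover_area_ha),
                "high_uncertainty_flag": flag_average_age(
                    avg_age, config.avg_age_flag_threshold),
            })

    report_years = set(config.report_years)
    emit(config.start_year, carbon_now())

    for step in range(1, config.horizon + 1):
        year = config.start_year + step
        # 1. grow
        ages[alive] += 1.0
        for cid in np.unique(species[alive]):
            m = alive & (species == cid)
            cls = registry[cid]
            dbh[m] = mix(ages[m]) if cls.family == "mix" else dbh_at_age(cls, ages[m])
        carbon_kg = carbon_now()

        # 2. prune (optional): removed share goes to the dead/residual pool
        if config.pruning_enabled and step % config.pruning_interval == 0:
            for u in uses:
                m = use_masks[u] & alive
                removed = config.pruning_fraction * float(carbon_kg[m].sum())
                if expected:
                    removed *= weights[u]
                dead_pool_kg[u] += removed
            carbon_kg = carbon_kg * (1.0 - config.pruning_fraction)

        # 3. mortality: dying trees carry current-year carbon into the dead pool
        for u, rate in mortality.rates.items():
            m = use_masks[u] & alive
            if not m.any() or rate == 0:
                continue
            if expected:
                dead_pool_kg[u] += (weights[u] * rate) * float(carbon_kg[m].sum())
                weights[u] *= 1.0 - rate
            else:
                idx = np.flatnonzero(m)
                dies = idx[rng.random(len(idx)) < rate]
                dead_pool_kg[u] += float(carbon_kg[dies].sum())
                alive[dies] = False

        if year in report_years:
            emit(year, carbon_kg)

    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return report
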