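"""Stratified annual mortality, population half-life, planting scenarios.

Mortality is a static annual rate per land-use class (street 3.5%/y,
mixed 2%/y, park 1%/y by default), applied by stratified random selection
of individual trees.  Two modes:

* ``stochastic`` — every alive tree dies this year independently with its
  class rate (Bernoulli thinning).
* ``expected_value`` — deterministic expectation accounting.  Because the
  rate depends only on the land-use class, every tree of class ``c`` has
  survival probability ``(1 - m_c)**t`` after ``t`` years, so expected
  populations and carbon pools are computed exactly (continuous,
  fractional counts); integer deaths ``round(m_c * alive_c)`` are drawn
  only to keep per-record ``death_year`` bookkeeping meaningful.

The population half-life under a static rate ``m`` is the smallest whole
number of years ``t`` with ``(1 - m)**t <= 0.5``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allometry import (
    AllometryTable,
    DEFAULT_CARBON_FRACTION,
    mix_biomass_from_dbh,
)
from .growth import SpeciesRegistry, mix_curve

__all__ = [
    "MortalityModel",
    "PlantingScenario",
    "apply_annual_mortality",
    "population_half_life",
    "run_planting_scenario",
    "compensation_analysis",
]

KG_PER_KT = 1e6


@dataclass
class MortalityModel:
    """Annual mortality rates per land-use class plus the selection mode."""

    rate_street: float = 0.035
    rate_mixed: float = 0.02
    rate_park: float = 0.01
    mode: str = "stochastic"  # or "expected_value"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in self.rates.items():
            if not 0 <= rate < 1:
                raise ValueError(f"rate for {name!r} must be in [0, 1), got {rate}")
        if self.mode not in ("stochastic", "expected_value"):
            raise ValueError(f"unknown mortality mode {self.mode!r}")

    @property
    def rates(self) -> dict[str, float]:
        return {
            "street": self.rate_street,
            "mixed": self.rate_mixed,
            "park": self.rate_park,
        }


@dataclass
class PlantingScenario:
    """A single planted cohort: mix-class trees grown under one static rate."""

    n_trees: int = 100_000
    growth_horizon: int = 70
    mortality_rate: float = 0.035
    start_age: float = 0.0
    mode: str = "expected_value"
    carbon_fraction: float = DEFAULT_CARBON_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 0:
            raise ValueError("n_trees must be >= 0")
        if self.growth_horizon < 1:
            raise ValueError("growth_horizon must be >= 1")
        if not 0 <= self.mortality_rate < 1:
            raise ValueError("mortality_rate must be in [0, 1)")
        if self.mode not in ("stochastic", "expected_value"):
            raise ValueError(f"unknown scenario mode {self.mode!r}")


def apply_annual_mortality(
    inventory: pd.DataFrame,
    model: MortalityModel,
    year: int,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply one year of stratified mortality; return (inventory, newly dead).

    The inventory is updated in place (``alive`` flag and ``death_year``);
    trees already dead are never touched.  In ``expected_value`` mode
    exactly ``round(rate_c * alive_c)`` trees die per class, chosen by a
    seeded draw.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    known = set(model.rates)
    labels = set(inventory["land_use"].unique())
    unknown = labels - known
    if unknown:
        offender = inventory[inventory["land_use"].isin(unknown)].iloc[0]
        raise ValueError(
            f"unknown land_use {offender['land_use']!r} for tree_id "
            f"{offender['tree_id']}"
        )

    alive_mask = inventory["alive"].to_numpy(dtype=bool)
    dying = np.zeros(len(inventory), dtype=bool)
    for use, rate in model.rates.items():
        idx = np.flatnonzero(alive_mask & (inventory["land_use"] == use).to_numpy())
        if len(idx) == 0 or rate == 0:
            continue
        if model.mode == "stochastic":
            dying[idx[rng.random(len(idx)) < rate]] = True
        else:
            n_die = int(round(rate * len(idx)))
            if n_die:
                dying[rng.choice(idx, size=n_die, replace=False)] = True

    newly_dead = inventory.loc[dying].copy()
    inventory.loc[dying, "alive"] = False
    inventory.loc[dying, "death_year"] = year
    return inventory, newly_dead


def population_half_life(rate: float) -> int:
    """Years until half a cohort is dead: smallest ``t`` with ``(1-m)^t <= 0.5``.

    For the default street/mixed/park rates (3.5%, 2%, 1%) this gives 20,
    35 and 69 years.  Rates >= 1 kill everything in the first year.
    """
    if rate <= 0:
        raise ValueError("half-life undefined for rate <= 0")
    if rate >= 1:
        return 1
    t = math.ceil(math.log(0.5) / math.log1p(-rate))
    # guard against floating-point edge cases around integer solutions
    while (1.0 - rate) ** (t - 1) <= 0.5 and t > 1:
        t -= 1
    while (1.0 - rate) ** t > 0.5:
        t += 1
    return t


def run_planting_scenario(
    scenario: PlantingScenario,
    allometry: AllometryTable,
    registry: SpeciesRegistry | None = None,
) -> pd.DataFrame:
    """Simulate a planted mix-class cohort year by year.

    Returns a DataFrame over years ``0..growth_horizon`` with columns
    ``year``, ``age_years``, ``dbh_cm``, ``alive_count`` (continuous in
    expected-value mode), ``alive_carbon_ktC`` and ``is_half_life_year``
    (the year flagged by :func:`population_half_life`, or never for a zero
    rate).
    """
    from .growth import load_default_registry

    registry = registry or load_default_registry()
    curve = mix_curve(registry)
    rng = np.random.default_rng(scenario.seed)
    m = scenario.mortality_rate
    half_life = population_half_life(m) if m > 0 else None

    years = np.arange(scenario.growth_horizon + 1)
    ages = scenario.start_age + years
    dbhs = curve(ages.astype(float))
    per_tree_carbon = scenario.carbon_fraction * mix_biomass_from_dbh(
        allometry, registry, dbhs
    )

    alive = np.empty(len(years))
    alive[0] = scenario.n_trees
    for t in range(1, len(years)):
        if scenario.mode == "expected_value":
            alive[t] = alive[t - 1] * (1.0 - m)
        else:
            alive[t] = rng.binomial(int(alive[t - 1]), 1.0 - m)

    return pd.DataFrame({
        "year": years,
        "age_years": ages,
        "dbh_cm": dbhs,
        "alive_count": alive,
        "alive_carbon_ktC": alive * per_tree_carbon / KG_PER_KT,
        "is_half_life_year": years == half_life if half_life is not None else False,
    })


def compensation_analysis(
    lca_report: pd.DataFrame,
    trajectory: pd.DataFrame,
    rates: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Compare each class's alive-carbon decline with planting-scenario carbon.

    For every land-use class, the decline in alive carbon between the LCA
    start and that class's population half-life year is set against the
    scenario's alive carbon at the same year; the ratio says how many times
    larger the planting initiative would need to be to compensate the loss
    (negative declines mean the class gained carbon).  Purely arithmetic on
    its inputs.
    """
    rates = rates or MortalityModel().rates
    rows = []
    start_year = int(lca_report["year"].min())
    for use, rate in rates.items():
        h = population_half_life(rate)
        target_year = start_year + h
        cls = lca_report[lca_report["land_use"] == use]
        if (target_year not in cls["year"].values
                or h not in trajectory["year"].values):
            raise ValueError(
                f"half-life year {h} for class {use!r} is outside the "
                "compared period of the report or trajectory"
            )
        start_c = float(cls.loc[cls["year"] == start_year, "alive_ktC"].iloc[0])
        end_c = float(cls.loc[cls["year"] == target_year, "alive_ktC"].iloc[0])
        scenario_c = float(
            trajectory.loc[trajectory["year"] == h, "alive_carbon_ktC"].iloc[0]
        )
        decline = start_c - end_c
        rows.append({
            "land_use": use,
            "half_life_years": h,
            "alive_carbon_decline_ktC": decline,
            "scenario_carbon_at_half_life_ktC": scenario_c,
            "compensation_ratio": decline / scenario_c if scenario_c else np.inf,
        })
    return pd.DataFrame(rows)
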