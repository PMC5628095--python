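"""Synthetic per-tree inventory generation and summaries.

The real input this package targets is a remotely sensed individual-tree
inventory (about 1.4 million trees city-wide, mean height 15 m, mean DBH
36 cm) which is not publicly deposited.  This module generates synthetic
inventories with the same statistical structure so the whole life-cycle
pipeline is exercisable: species classes drawn from the canopy fractions,
land-use classes (street / mixed / park) from a configurable split, ages
from per-class truncated normals (street 49 +/- 15 y, mixed 52 +/- 17 y,
park 56 +/- 15 y, floored at 1 y), and DBH derived from age through the
species growth curves.  Mean DBH is therefore *implied* by the age
structure and the curves (low-to-mid 30s cm at mean age 52) rather than
forced; a calibration check warns when it leaves a +/-15% band around the
remotely sensed 36 cm.

An inventory is a pandas DataFrame with one row per tree (columns in
:data:`INVENTORY_COLUMNS`); dead trees carry a ``death_year``, live trees
do not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .allometry import DEFAULT_CARBON_FRACTION
from .growth import SpeciesRegistry, dbh_at_age, load_default_registry, mix_curve

__all__ = [
    "InventoryConfig",
    "generate_inventory",
    "summarize_inventory",
    "read_inventory_csv",
    "write_inventory_csv",
    "INVENTORY_COLUMNS",
]

INVENTORY_COLUMNS = [
    "tree_id", "species_class", "land_use", "age_years", "dbh_cm",
    "height_m", "x", "y", "alive", "death_year",
]

LAND_USES = ("street", "mixed", "park")

#: Remotely sensed city-wide mean DBH used as a soft calibration anchor (cm).
REFERENCE_MEAN_DBH_CM = 36.0
CALIBRATION_BAND = 0.15

# Default per-land-use age distributions: mean, SD (years), truncated at >= 1.
DEFAULT_AGE_DISTRIBUTIONS = {
    "street": (49.0, 15.0),
    "mixed": (52.0, 17.0),
    "park": (56.0, 15.0),
}

# Shipped default street/mixed/park split; a configuration default, not an
# observed city-wide value.
DEFAULT_CLASS_PROPORTIONS = {"street": 0.20, "mixed": 0.45, "park": 0.35}


@dataclass
class InventoryConfig:
    """Configuration for synthetic-inventory generation.

    ``species_probabilities`` defaults to the canopy fractions of the
    packaged species table (classes without a printed fraction are covered
    by the mix class).  ``age_distributions`` maps land use to
    ``(mean, sd)`` of a normal truncated at ``min_age``.
    """

    n_trees: int = 100_000
    species_probabilities: dict[str, float] | None = None
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    age_distributions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AGE_DISTRIBUTIONS))
    min_age: float = 1.0
    dbh_noise: bool = False
    with_heights: bool = True
    with_coordinates: bool = False
    calibration_check: bool = False
    seed: int = 0

    def validate(self, registry: SpeciesRegistry) -> dict[str, float]:
        """Check probability vectors; return resolved species probabilities."""
        probs = self.species_probabilities
        if probs is None:
            probs = registry.canopy_probabilities()
        else:
            probs = {str(k): float(v) for k, v in probs.items()}
        if any(v < 0 for v in probs.values()) or abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError(
                "species_probabilities must be non-negative and sum to 1"
            )
        unknown = set(probs) - set(registry.class_ids)
        if unknown:
            raise ValueError(f"species_probabilities has unknown classes {sorted(unknown)}")
        lu = self.class_proportions
        if set(lu) != set(LAND_USES):
            raise ValueError(f"class_proportions must cover exactly {LAND_USES}")
        if any(v < 0 for v in lu.values()) or abs(sum(lu.values()) - 1.0) > 1e-9:
            raise ValueError("class_proportions must be non-negative and sum to 1")
        for use, (mean, sd) in self.age_distributions.items():
            if sd <= 0:
                raise ValueError(f"age SD for {use!r} must be > 0")
        if self.n_trees < 0:
            raise ValueError("n_trees must be >= 0")
        return probs


def _truncated_normal_ages(rng, n, mean, sd, lower):
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def _heights_from_dbh(dbh):
    # Monotone height-DBH rule for completeness only; the carbon path is
    # DBH-only and never reads heights.
    return 1.3 + 0.95 * np.asarray(dbh, dtype=float) ** 0.72


def generate_inventory(
    config: InventoryConfig,
    registry: SpeciesRegistry | None = None,
) -> pd.DataFrame:
    """Draw a synthetic all-alive tree inventory (deterministic per seed)."""
    registry = registry or load_default_registry()
    probs = config.validate(registry)
    rng = np.random.default_rng(config.seed)
    n = config.n_trees

    class_ids = np.array(list(probs))
    species = rng.choice(class_ids, size=n, p=np.array(list(probs.values())))
    uses = np.array(LAND_USES)
    lu_p = np.array([config.class_proportions[u] for u in LAND_USES])
    land_use = rng.choice(uses, size=n, p=lu_p)

    ages = np.empty(n)
    for use in LAND_USES:
        mask = land_use == use
        mean, sd = config.age_distributions[use]
        ages[mask] = _truncated_normal_ages(rng, int(mask.sum()), mean, sd, config.min_age)

    dbh = np.empty(n)
    mix = mix_curve(registry)
    for cid in np.unique(species):
        mask = species == cid
        cls = registry[cid]
        if cls.family == "mix":
            dbh[mask] = mix(ages[mask])
        else:
            dbh[mask] = dbh_at_age(cls, ages[mask])
        if config.dbh_noise and cls.residual_error:
            dbh[mask] = np.maximum(
                dbh[mask] + rng.normal(0.0, cls.residual_error, int(mask.sum())), 0.0
            )

    frame = pd.DataFrame({
        "tree_id": np.arange(n, dtype=np.int64),
        "species_class": species,
        "land_use": land_use,
        "age_years": ages,
        "dbh_cm": dbh,
        "height_m": _heights_from_dbh(dbh) if config.with_heights else np.nan,
        "x": rng.uniform(0, 30_000, n) if config.with_coordinates else np.nan,
        "y": rng.uniform(0, 30_000, n) if config.with_coordinates else np.nan,
        "alive": np.ones(n, dtype=bool),
        "death_year": pd.array([pd.NA] * n, dtype="Int64"),
    })

    if config.calibration_check and n > 0:
        mean_dbh = float(frame["dbh_cm"].mean())
        lo = REFERENCE_MEAN_DBH_CM * (1 - CALIBRATION_BAND)
        hi = REFERENCE_MEAN_DBH_CM * (1 + CALIBRATION_BAND)
        if not lo <= mean_dbh <= hi:
            warnings.warn(
                f"generated mean DBH {mean_dbh:.1f} cm falls outside the "
                f"calibration band [{lo:.1f}, {hi:.1f}] cm around the remotely "
                f"sensed reference {REFERENCE_MEAN_DBH_CM} cm",
                stacklevel=2,
            )
    return frame


def summarize_inventory(inventory: pd.DataFrame) -> dict:
    """Exact arithmetic summaries of an inventory.

    Returns counts, overall and per-land-use mean ages, mean DBH and species
    frequencies; an empty inventory yields an explicit empty summary.
    """
    if len(inventory) == 0:
        return {
            "n_trees": 0, "n_alive": 0, "mean_age": None, "mean_dbh": None,
            "mean_age_by_land_use": {}, "species_frequencies": {},
        }
    alive = inventory[inventory["alive"]]
    return {
        "n_trees": int(len(inventory)),
        "n_alive": int(len(alive)),
        "mean_age": float(inventory["age_years"].mean()),
        "mean_dbh": float(inventory["dbh_cm"].mean()),
        "mean_age_by_land_use": inventory.groupby("land_use", observed=True)[
            "age_years"].mean().to_dict(),
        "species_frequencies": (
            inventory["species_class"].value_counts(normalize=True).to_dict()
        ),
    }


def _validate_inventory(frame: pd.DataFrame, origin: str = "inventory") -> None:
    missing = set(INVENTORY_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{origin}: missing column(s) {sorted(missing)}")
    bad_age = frame.index[frame["age_years"] < 0]
    if len(bad_age):
        raise ValueError(f"{origin}: negative age at line {bad_age[0] + 2}")
    bad_dbh = frame.index[frame["dbh_cm"] < 0]
    if len(bad_dbh):
        raise ValueError(f"{origin}: negative dbh at line {bad_dbh[0] + 2}")
    alive = frame["alive"].astype(bool)
    dead_missing = frame.index[~alive & frame["death_year"].isna()]
    if len(dead_missing):
        raise ValueError(
            f"{origin}: dead tree without death_year at line {dead_missing[0] + 2}"
        )
    alive_with = frame.index[alive & frame["death_year"].notna()]
    if len(alive_with):
        raise ValueError(
            f"{origin}: alive tree with death_year at line {alive_with[0] + 2}"
        )


def write_inventory_csv(inventory: pd.DataFrame, path: str | Path) -> None:
    inventory.to_csv(path, index=False)


def read_inventory_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate an inventory CSV (errors report 1-based line numbers)."""
    frame = pd.read_csv(
        path,
        dtype={"species_class": str, "land_use": str},
    )
    if "death_year" in frame.columns:
        frame["death_year"] = frame["death_year"].astype("Int64")
    if "alive" in frame.columns:
        frame["alive"] = frame["alive"].astype(bool)
    _validate_inventory(frame, origin=str(path))
    return frame
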