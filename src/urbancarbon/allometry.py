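"""Allometric above-ground biomass models and the biomass-to-carbon step.

Above-ground dry biomass (kg) is predicted from DBH (cm) through power-law
allometries ``biomass = a * dbh**c``.  Species-specific published equations
vary widely between sources, so the table is pluggable: each species class
references an ``allometry_key`` and any CSV with the right columns can be
swapped in.  The packaged defaults are two synthetic generic temperate
power laws (one broadleaf, one conifer) — implementation defaults, clearly
not species-calibrated equations — so absolute pool magnitudes depend on
the table supplied while demography (counts, ages, half-lives) does not.

Carbon is a fixed fraction of dry biomass, 0.5 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AllometricModel",
    "AllometryTable",
    "biomass_from_dbh",
    "mix_biomass_from_dbh",
    "carbon_from_biomass",
    "load_default_allometry",
]

logger = logging.getLogger(__name__)

DEFAULT_CARBON_FRACTION = 0.5


@dataclass(frozen=True)
class AllometricModel:
    """A single power-law biomass model, ``biomass_kg = a * dbh_cm**c``."""

    allometry_key: str
    form: str = "power_law"
    coeff_a: float = 0.0
    exponent_c: float = 0.0
    valid_dbh_range: tuple[float, float] = (0.0, np.inf)
    source: str = ""

    def __post_init__(self) -> None:
        if self.form != "power_law":
            raise ValueError(f"unsupported allometric form {self.form!r}")
        if self.coeff_a <= 0 or self.exponent_c <= 0:
            raise ValueError(
                f"allometry {self.allometry_key!r}: coefficients must be > 0"
            )


class AllometryTable:
    """Mapping ``allometry_key -> AllometricModel`` plus the mix rule."""

    def __init__(self, models: list[AllometricModel]):
        self._models = {m.allometry_key: m for m in models}
        if len(self._models) != len(models):
            raise ValueError("duplicate allometry_key in table")

    def __getitem__(self, key: str) -> AllometricModel:
        try:
            return self._models[key]
        except KeyError:
            raise KeyError(
                f"allometry_key {key!r} does not resolve in the allometry table"
            ) from None

    def __contains__(self, key: str) -> bool:
        return key in self._models

    def keys(self):
        return self._models.keys()

    def resolve_registry(self, registry) -> dict[str, AllometricModel]:
        """Map every non-mix species class to its model; raise on any gap."""
        out = {}
        for cls in registry.species_classes:
            out[cls.class_id] = self[cls.allometry_key]
        return out

    @classmethod
    def from_csv(cls, path: str | Path) -> "AllometryTable":
        table = pd.read_csv(path)
        required = {"allometry_key", "form", "coeff_a", "exponent_c",
                    "dbh_min_cm", "dbh_max_cm", "source"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"allometry table missing columns: {sorted(missing)}")
        models = [
            AllometricModel(
                allometry_key=row.allometry_key,
                form=row.form,
                coeff_a=float(row.coeff_a),
                exponent_c=float(row.exponent_c),
                valid_dbh_range=(
                    0.0 if pd.isna(row.dbh_min_cm) else float(row.dbh_min_cm),
                    np.inf if pd.isna(row.dbh_max_cm) else float(row.dbh_max_cm),
                ),
                source="" if pd.isna(row.source) else str(row.source),
            )
            for row in table.itertuples()
        ]
        return cls(models)


def load_default_allometry() -> AllometryTable:
    """Load the packaged generic broadleaf/conifer power-law table."""
    with resources.as_file(
        resources.files("urbancarbon.data") / "allometry_default.csv"
    ) as path:
        return AllometryTable.from_csv(path)


def biomass_from_dbh(model: AllometricModel, dbh) -> np.ndarray | float:
    """Above-ground dry biomass (kg) at ``dbh`` cm (scalar or array).

    Diameters outside the model's stated validity range are still evaluated
    (totals stay smooth) but logged at DEBUG level.
    """
    dbh_arr = np.asarray(dbh, dtype=float)
    if np.any(dbh_arr < 0):
        raise ValueError("dbh must be >= 0")
    lo, hi = model.valid_dbh_range
    n_out = int(np.count_nonzero((dbh_arr < lo) | (dbh_arr > hi)))
    if n_out:
        logger.debug(
            "%d DBH value(s) outside the validity range [%g, %g] of %s",
            n_out, lo, hi, model.allometry_key,
        )
    out = model.coeff_a * dbh_arr ** model.exponent_c
    return float(out) if dbh_arr.ndim == 0 else out


def mix_biomass_from_dbh(table: AllometryTable, registry, dbh) -> np.ndarray | float:
    """Mix-class biomass: unweighted mean over the ten class models at ``dbh``."""
    models = list(table.resolve_registry(registry).values())
    dbh_arr = np.asarray(dbh, dtype=float)
    stacked = np.stack([biomass_from_dbh(m, dbh_arr) for m in models])
    out = stacked.mean(axis=0)
    return float(out) if dbh_arr.ndim == 0 else out


def carbon_from_biomass(biomass, fraction: float = DEFAULT_CARBON_FRACTION):
    """Convert above-ground dry biomass (kg) to carbon (kg C).

    The default fraction 0.5 is the standard dry-biomass-to-carbon factor;
    it is configurable through the LCA configuration.
    """
    b = np.asarray(biomass, dtype=float)
    if np.any(b < 0):
        raise ValueError("biomass must be >= 0")
    if not 0 < fraction <= 1:
        raise ValueError("carbon fraction must be in (0, 1]")
    out = fraction * b
    return float(out) if b.ndim == 0 else out
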