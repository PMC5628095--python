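"""Species-specific DBH-age growth curves and their inverses.

Two bounded growth families describe stem diameter (DBH, cm) as a function
of tree age (years):

* saturating (Chapman-Richards form):  ``dbh = A * (1 - exp(-k*age))**p``
* Gompertz:                            ``dbh = A * exp(-b * exp(-k*age))``

Both are strictly increasing in age and approach the asymptote ``A`` from
below.  The saturating family starts at 0 cm; the Gompertz family starts at
``A*exp(-b)`` (a small but nonzero sapling diameter).  An eleventh "mix"
class, covering trees that could not be assigned a dominant species, is the
unweighted arithmetic mean of the ten species curves.

The packaged registry holds the coefficients for the ten dominant species
classes of the Berlin street-tree canopy plus the mix class, together with
the regression residual errors (cm) and each class's fraction of the total
canopy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "SpeciesGrowthClass",
    "SpeciesRegistry",
    "GrowthDomainError",
    "dbh_at_age",
    "age_from_dbh",
    "mix_dbh_at_age",
    "mix_age_from_dbh",
    "load_default_registry",
]

#: Relative cap below the asymptote used when inverting an unattainable DBH.
DEFAULT_CAP_EPSILON = 1e-3


class GrowthDomainError(ValueError):
    """Raised for ages or diameters outside a growth curve's domain."""


@dataclass(frozen=True)
class SpeciesGrowthClass:
    """One species class: growth family, coefficients and canopy metadata.

    Parameters follow the growth-curve families above.  ``shape_p`` is used
    only by the saturating family and ``offset_b`` only by the Gompertz
    family; the unused one is ``None``.  ``canopy_fraction`` is the class's
    percentage of total tree canopy and may be ``None`` for minor classes
    that are folded into the mix class.
    """

    class_id: str
    label: str
    family: str  # "saturating" | "gompertz" | "mix"
    asymptote_A: float | None = None
    rate_k: float | None = None
    shape_p: float | None = None
    offset_b: float | None = None
    residual_error: float | None = None
    canopy_fraction: float | None = None
    allometry_key: str = ""

    def __post_init__(self) -> None:
        if self.family not in ("saturating", "gompertz", "mix"):
            raise ValueError(f"unknown growth family {self.family!r}")
        if self.family == "mix":
            if self.asymptote_A is not None:
                raise ValueError("mix class carries no coefficients of its own")
            return
        if self.asymptote_A is None or self.asymptote_A <= 0:
            raise ValueError(f"class {self.class_id}: asymptote must be > 0")
        if self.rate_k is None or self.rate_k <= 0:
            raise ValueError(f"class {self.class_id}: rate k must be > 0")
        if self.family == "saturating" and (self.shape_p is None or self.shape_p <= 0):
            raise ValueError(f"class {self.class_id}: shape p must be > 0")
        if self.family == "gompertz" and (self.offset_b is None or self.offset_b <= 0):
            raise ValueError(f"class {self.class_id}: offset b must be > 0")

    @property
    def dbh_at_age_zero(self) -> float:
        """DBH at age 0: zero for saturating, ``A*exp(-b)`` for Gompertz."""
        if self.family == "gompertz":
            return float(self.asymptote_A * np.exp(-self.offset_b))
        return 0.0


class SpeciesRegistry:
    """Ordered collection of the eleven species growth classes.

    Validates uniqueness of class ids and that the canopy fractions that are
    present sum to 100% (within 0.1).  Iteration order follows the input
    table.
    """

    def __init__(self, classes: list[SpeciesGrowthClass]):
        ids = [c.class_id for c in classes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate class_id in species registry")
        self._classes = {c.class_id: c for c in classes}
        fractions = [c.canopy_fraction for c in classes if c.canopy_fraction is not None]
        if fractions and abs(sum(fractions) - 100.0) > 0.1:
            raise ValueError(
                f"canopy fractions sum to {sum(fractions):.3f}, expected 100"
            )

    def __getitem__(self, class_id: str) -> SpeciesGrowthClass:
        return self._classes[str(class_id)]

    def __iter__(self):
        return iter(self._classes.values())

    def __len__(self) -> int:
        return len(self._classes)

    @property
    def species_classes(self) -> list[SpeciesGrowthClass]:
        """The non-mix classes, in registry order."""
        return [c for c in self._classes.values() if c.family != "mix"]

    @property
    def class_ids(self) -> list[str]:
        return list(self._classes)

    def canopy_probabilities(self) -> dict[str, float]:
        """Sampling probabilities from the canopy fractions that are present."""
        present = {
            c.class_id: c.canopy_fraction
            for c in self
            if c.canopy_fraction is not None
        }
        total = sum(present.values())
        return {cid: f / total for cid, f in present.items()}

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpeciesRegistry":
        table = pd.read_csv(path, dtype={"class_id": str})
        required = {"class_id", "label", "family", "A", "k", "p", "b",
                    "residual_error_cm", "canopy_fraction_pct", "allometry_key"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"species table missing columns: {sorted(missing)}")

        def opt(value):
            return None if pd.isna(value) else float(value)

        classes = [
            SpeciesGrowthClass(
                class_id=str(row.class_id),
                label=row.label,
                family=row.family,
                asymptote_A=opt(row.A),
                rate_k=opt(row.k),
                shape_p=opt(row.p),
                offset_b=opt(row.b),
                residual_error=opt(row.residual_error_cm),
                canopy_fraction=opt(row.canopy_fraction_pct),
                allometry_key=row.allometry_key,
            )
            for row in table.itertuples()
        ]
        return cls(classes)


def load_default_registry() -> SpeciesRegistry:
    """Load the packaged species table (ten dominant classes plus mix)."""
    with resources.as_file(
        resources.files("urbancarbon.data") / "species_growth.csv"
    ) as path:
        return SpeciesRegistry.from_csv(path)


def dbh_at_age(species: SpeciesGrowthClass, age) -> np.ndarray | float:
    """Evaluate a species growth curve at ``age`` years (scalar or array).

    Raises
    ------
    GrowthDomainError
        For negative ages or when called on the mix class (use
        :func:`mix_dbh_at_age` for that).
    """
    age_arr = np.asarray(age, dtype=float)
    if np.any(age_arr < 0):
        raise GrowthDomainError("age must be >= 0")
    if species.family == "mix":
        raise GrowthDomainError("mix class has no curve of its own; use mix_dbh_at_age")
    if species.family == "saturating":
        out = species.asymptote_A * (1.0 - np.exp(-species.rate_k * age_arr)) ** species.shape_p
    else:  # gompertz
        out = species.asymptote_A * np.exp(-species.offset_b * np.exp(-species.rate_k * age_arr))
    return float(out) if age_arr.ndim == 0 else out


def _capped_age(species: SpeciesGrowthClass, epsilon: float) -> float:
    """Age at which the curve reaches ``(1 - epsilon) * A``."""
    return _invert(species, (1.0 - epsilon) * species.asymptote_A)


def _invert(species: SpeciesGrowthClass, dbh: float) -> float:
    """Closed-form inverse on the curve's open range (no policy handling)."""
    A = species.asymptote_A
    if species.family == "saturating":
        return float(-np.log(1.0 - (dbh / A) ** (1.0 / species.shape_p)) / species.rate_k)
    return float(-np.log(-np.log(dbh / A) / species.offset_b) / species.rate_k)


def age_from_dbh(
    species: SpeciesGrowthClass,
    dbh,
    *,
    policy: str = "cap",
    epsilon: float = DEFAULT_CAP_EPSILON,
) -> np.ndarray | float:
    """Invert the growth curve: unique age at which the species reaches ``dbh``.

    Closed forms per family.  Diameters at or above the asymptote are
    unattainable; under the default ``policy="cap"`` they map, with a
    warning, to the age at which the curve reaches ``(1 - epsilon) * A``,
    while ``policy="strict"`` raises.  Diameters below the Gompertz age-0
    value clamp to age 0 with a warning.
    """
    if policy not in ("cap", "strict"):
        raise ValueError(f"unknown inversion policy {policy!r}")
    if species.family == "mix":
        raise GrowthDomainError("use mix_age_from_dbh for the mix class")
    dbh_arr = np.atleast_1d(np.asarray(dbh, dtype=float))
    if np.any(dbh_arr < 0):
        raise GrowthDomainError("dbh must be >= 0")

    A = species.asymptote_A
    over = dbh_arr >= A * (1.0 - epsilon)
    if np.any(over):
        if policy == "strict":
            raise GrowthDomainError(
                f"dbh {float(dbh_arr[over][0]):.2f} cm >= attainable bound of "
                f"asymptote {A:.2f} cm for class {species.class_id}"
            )
        warnings.warn(
            f"{int(over.sum())} DBH value(s) at/above the asymptote of class "
            f"{species.class_id} ({A:.1f} cm); capping age at the "
            f"(1-{epsilon:g})*A point",
            stacklevel=2,
        )
    floor = species.dbh_at_age_zero
    under = dbh_arr < floor
    if np.any(under):
        warnings.warn(
            f"{int(under.sum())} DBH value(s) below the age-0 diameter "
            f"({floor:.2f} cm) of class {species.class_id}; clamping to age 0",
            stacklevel=2,
        )

    clipped = np.clip(dbh_arr, floor, A * (1.0 - epsilon))
    if species.family == "saturating":
        ages = -np.log(1.0 - (clipped / A) ** (1.0 / species.shape_p)) / species.rate_k
        ages = np.where(clipped <= 0, 0.0, ages)
    else:
        # dbh > 0 guaranteed by the age-0 floor A*exp(-b) > 0
        ages = -np.log(-np.log(clipped / A) / species.offset_b) / species.rate_k
        ages = np.maximum(ages, 0.0)
    return ages if np.asarray(dbh).ndim else float(ages[0])


def mix_dbh_at_age(registry: SpeciesRegistry, age) -> np.ndarray | float:
    """Mix-class curve: unweighted mean DBH of the ten species curves.

    A canopy-fraction-weighted mean is available via ``weights="canopy"``
    on :func:`mix_curve`.
    """
    return mix_curve(registry)(age)


def mix_curve(registry: SpeciesRegistry, weights: str = "equal"):
    """Return a vectorised callable age -> mean DBH over the species classes.

    ``weights="equal"`` (default) is the plain average of the ten curves;
    ``weights="canopy"`` weights each present class by its canopy fraction.
    """
    classes = registry.species_classes
    if weights == "equal":
        w = np.full(len(classes), 1.0 / len(classes))
    elif weights == "canopy":
        raw = np.array([
            c.canopy_fraction if c.canopy_fraction is not None else 0.0
            for c in classes
        ])
        if raw.sum() <= 0:
            raise ValueError("no canopy fractions available for weighting")
        w = raw / raw.sum()
    else:
        raise ValueError(f"unknown weighting {weights!r}")

    def curve(age):
        age_arr = np.asarray(age, dtype=float)
        stacked = np.stack([dbh_at_age(c, age_arr) for c in classes])
        out = np.tensordot(w, stacked, axes=1)
        return float(out) if age_arr.ndim == 0 else out

    return curve


def mix_age_from_dbh(
    registry: SpeciesRegistry,
    dbh,
    *,
    policy: str = "cap",
    epsilon: float = DEFAULT_CAP_EPSILON,
    max_age: float = 2000.0,
) -> np.ndarray | float:
    """Numerically invert the mix curve (bracketed root find, tol 1e-6 cm).

    The averaged curve has no closed-form inverse, so ages are found with
    Brent's method on ``[0, max_age]``.  Diameters outside the attainable
    range follow the same cap/clamp policy as :func:`age_from_dbh`, with the
    asymptote taken as the mean of the ten species asymptotes.
    """
    curve = mix_curve(registry)
    classes = registry.species_classes
    mean_asymptote = float(np.mean([c.asymptote_A for c in classes]))
    floor = curve(0.0)

    dbh_arr = np.atleast_1d(np.asarray(dbh, dtype=float))
    if np.any(dbh_arr < 0):
        raise GrowthDomainError("dbh must be >= 0")

    cap_dbh = (1.0 - epsilon) * mean_asymptote
    cap_dbh = min(cap_dbh, curve(max_age) - 1e-9)
    over = dbh_arr >= cap_dbh
    if np.any(over):
        if policy == "strict":
            raise GrowthDomainError(
                f"dbh {float(dbh_arr[over][0]):.2f} cm is unattainable for the mix "
                f"curve (mean asymptote {mean_asymptote:.2f} cm)"
            )
        warnings.warn(
            f"{int(over.sum())} DBH value(s) at/above the attainable mix-curve "
            "range; capping age",
            stacklevel=2,
        )
    under = dbh_arr < floor
    if np.any(under):
        warnings.warn(
            f"{int(under.sum())} DBH value(s) below the mix-curve age-0 diameter "
            f"({floor:.2f} cm); clamping to age 0",
            stacklevel=2,
        )

    clipped = np.clip(dbh_arr, floor, cap_dbh)
    ages = np.empty_like(clipped)
    for i, target in enumerate(clipped):
        if target <= floor:
            ages[i] = 0.0
        else:
            ages[i] = brentq(lambda a: curve(a) - target, 0.0, max_age, xtol=1e-9)
    return ages if np.asarray(dbh).ndim else float(ages[0])
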