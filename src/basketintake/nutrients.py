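"""Nutrient vectors and energy-adjusted (relative) dietary composition.

Six analytes are carried through every pipeline stage: energy (kcal),
total sugars (g), protein (g), total fat (g), saturated fat (g) and
sodium (mg). Macronutrients are energy-adjusted by converting grams to
kcal with Atwater-style factors (protein 4, fat 9, saturated fat 9,
sugars 3.9 kcal/g) and expressing the result as a percentage of total
energy; sodium is expressed as a density in mg per kcal. Relative
measures are invariant to any uniform rescaling of the vector, which is
why an individual's household-share allocation leaves them unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .errors import DataError, UndefinedCompositionError

#: CSV/DataFrame column names for the six analytes, in canonical order.
NUTRIENT_FIELDS: tuple[str, ...] = (
    "energy_kcal",
    "sugars_g",
    "protein_g",
    "fat_g",
    "satfat_g",
    "sodium_mg",
)

#: kcal contributed per gram of each macronutrient. Sugars use 3.9, not
#: the conventional 4; total and saturated fat share the same factor.
ENERGY_KCAL_PER_G: dict[str, float] = {
    "sugars": 3.9,
    "protein": 4.0,
    "fat": 9.0,
    "satfat": 9.0,
}


@dataclass(frozen=True)
class NutrientVector:
    """Daily (or total) amounts of the six analytes.

    Supports componentwise addition and scalar multiplication so that
    transaction lines can be summed and household estimates scaled by an
    allocation share.
    """

    energy_kcal: float = 0.0
    sugars_g: float = 0.0
    protein_g: float = 0.0
    fat_g: float = 0.0
    satfat_g: float = 0.0
    sodium_mg: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise DataError(f"NutrientVector.{f.name} must be finite and >= 0, got {v!r}")
        if self.satfat_g > self.fat_g * (1 + 1e-9):
            raise DataError(
                f"saturated fat ({self.satfat_g} g) cannot exceed total fat ({self.fat_g} g)"
            )

    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        return NutrientVector(*(a + b for a, b in zip(self.as_tuple(), other.as_tuple())))

    def __mul__(self, scalar: float) -> "NutrientVector":
        return NutrientVector(*(a * scalar for a in self.as_tuple()))

    __rmul__ = __mul__

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, f) for f in NUTRIENT_FIELDS)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.as_tuple(), dtype=float)

    @classmethod
    def from_array(cls, arr) -> "NutrientVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(NUTRIENT_FIELDS),):
            raise DataError(f"expected {len(NUTRIENT_FIELDS)} components, got shape {arr.shape}")
        return cls(*arr.tolist())

    def isclose(self, other: "NutrientVector", rtol: float = 1e-9, atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.as_array(), other.as_array(), rtol=rtol, atol=atol))


ZERO = NutrientVector()


@dataclass(frozen=True)
class RelativeProfile:
    """Energy-adjusted composition: four %-of-energy terms and Na density."""

    sugars_pctE: float
    protein_pctE: float
    fat_pctE: float
    satfat_pctE: float
    sodium_density: float  # mg per kcal

    #: field order used when relative measures are iterated in tables
    MEASURES = ("sugars_pctE", "protein_pctE", "fat_pctE", "satfat_pctE", "sodium_density")

    def as_tuple(self) -> tuple[float, ...]:
        return (
            self.sugars_pctE,
            self.protein_pctE,
            self.fat_pctE,
            self.satfat_pctE,
            self.sodium_density,
        )


def percent_energy(nutrient_g: float, energy_kcal: float, nutrient: str) -> float:
    """Percentage of total energy contributed by a macronutrient.

    ``nutrient`` is one of ``sugars``, ``protein``, ``fat``, ``satfat``
    (a trailing ``_g`` is tolerated). 100 * factor * grams / kcal.
    """
    key = nutrient.removesuffix("_g")
    if key not in ENERGY_KCAL_PER_G:
        raise DataError(f"unknown macronutrient {nutrient!r}; expected one of {sorted(ENERGY_KCAL_PER_G)}")
    if not energy_kcal > 0:
        raise UndefinedCompositionError(
            f"percent energy undefined at energy_kcal={energy_kcal!r} (must be > 0)"
        )
    if nutrient_g < 0:
        raise DataError(f"nutrient grams must be >= 0, got {nutrient_g!r}")
    return 100.0 * ENERGY_KCAL_PER_G[key] * nutrient_g / energy_kcal


def sodium_density(sodium_mg: float, energy_kcal: float) -> float:
    """Sodium density in mg per kcal of total energy."""
    if not energy_kcal > 0:
        raise UndefinedCompositionError(
            f"sodium density undefined at energy_kcal={energy_kcal!r} (must be > 0)"
        )
    if sodium_mg < 0:
        raise DataError(f"sodium_mg must be >= 0, got {sodium_mg!r}")
    return sodium_mg / energy_kcal


def relative_profile(v: NutrientVector) -> RelativeProfile:
    """Energy-adjusted profile of a nutrient vector.

    Scale-invariant: ``relative_profile(c * v) == relative_profile(v)``
    for any c > 0, so household-level and allocated individual-level
    purchase estimates share one relative profile. Raises
    :class:`UndefinedCompositionError` at zero energy rather than
    returning zeros.
    """
    e = v.energy_kcal
    return RelativeProfile(
        sugars_pctE=percent_energy(v.sugars_g, e, "sugars"),
        protein_pctE=percent_energy(v.protein_g, e, "protein"),
        fat_pctE=percent_energy(v.fat_g, e, "fat"),
        satfat_pctE=percent_energy(v.satfat_g, e, "satfat"),
        sodium_density=sodium_density(v.sodium_mg, e),
    )


def relative_profile_frame(df, prefix: str = "", out_prefix: str = "") -> "pd.DataFrame":
    """Vectorised relative profiles for a DataFrame of nutrient columns.

    Expects columns ``{prefix}energy_kcal`` ... ``{prefix}sodium_mg``;
    returns a DataFrame with ``{out_prefix}sugars_pctE`` etc. Rows with
    non-positive energy get NaN (the scalar API raises instead; a bulk
    table flags them for the exclusion ledger rather than aborting).
    """
    import pandas as pd

    e = df[f"{prefix}energy_kcal"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = pd.DataFrame(
            {
                f"{out_prefix}sugars_pctE": 100.0 * 3.9 * df[f"{prefix}sugars_g"] / e,
                f"{out_prefix}protein_pctE": 100.0 * 4.0 * df[f"{prefix}protein_g"] / e,
                f"{out_prefix}fat_pctE": 100.0 * 9.0 * df[f"{prefix}fat_g"] / e,
                f"{out_prefix}satfat_pctE": 100.0 * 9.0 * df[f"{prefix}satfat_g"] / e,
                f"{out_prefix}sodium_density": df[f"{prefix}sodium_mg"] / e,
            },
            index=df.index,
        )
    out[e <= 0] = np.nan
    return out
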