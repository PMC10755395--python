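"""Household-to-individual allocation of purchased nutrients.

Purchases are recorded per loyalty-card household; dietary intake is
per person. Household daily nutrient estimates are attributed to the
study participant in proportion to UK recommended daily energy intakes
by age and gender. The participant's own gender is known; other
household members' genders are not, so they receive the arithmetic
mean of the female and male recommendations for their age band.

Worked example: a 30-year-old woman living with a 30-year-old partner
(gender unknown) and a 3-year-old child is allocated
1928 / (1928 + 2230 + 1197.5) = 36 % of household purchased nutrients.

The recommendation table ships as a CSV (age_min, age_max, female_kcal,
male_kcal) approximating UK dietary reference values; users holding the
exact official table can supply their own file with the same schema.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, TableCoverageError
from .nutrients import NutrientVector

GENDERS = ("female", "male", "unknown")


@dataclass(frozen=True)
class HouseholdMember:
    """One person in a household: age in whole years and gender.

    ``gender`` is ``"female"``/``"male"`` for study participants and
    ``"unknown"`` for other household members.
    """

    age_years: int
    gender: str = "unknown"

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise DataError(f"age_years must be >= 0, got {self.age_years}")
        if self.gender not in GENDERS:
            raise DataError(f"gender must be one of {GENDERS}, got {self.gender!r}")


def load_recommendation_table(path=None) -> pd.DataFrame:
    """Load and validate an energy-recommendation table.

    With no ``path``, the packaged default table is used. Bands must be
    non-overlapping, contiguous and cover ages 0-120; recommendations
    must be strictly positive.
    """
    if path is None:
        with resources.files("basketintake.data").joinpath("energy_recommendations.csv").open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    required = ["age_min", "age_max", "female_kcal", "male_kcal"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ConfigurationError(f"recommendation table missing columns {missing}")
    table = table.sort_values("age_min").reset_index(drop=True)
    if (table["female_kcal"] <= 0).any() or (table["male_kcal"] <= 0).any():
        raise ConfigurationError("recommendation table: all kcal values must be > 0")
    if (table["age_max"] < table["age_min"]).any():
        raise ConfigurationError("recommendation table: age_max < age_min in some band")
    if table.loc[0, "age_min"] != 0 or table["age_max"].iloc[-1] < 120:
        raise ConfigurationError("recommendation table must cover ages 0-120")
    gaps = table["age_min"].iloc[1:].to_numpy() - table["age_max"].iloc[:-1].to_numpy()
    if (gaps != 1).any():
        raise ConfigurationError("recommendation table bands must be contiguous and non-overlapping")
    return table


_DEFAULT_TABLE: pd.DataFrame | None = None


def default_recommendation_table() -> pd.DataFrame:
    """The packaged default table (cached)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_recommendation_table()
    return _DEFAULT_TABLE


def recommended_energy(age_years: float, gender: str, table: pd.DataFrame | None = None) -> float:
    """Recommended daily energy intake (kcal) for an age and gender.

    ``gender="unknown"`` returns the mean of the female and male values
    for the age band, the convention for household members whose gender
    was not collected.
    """
    if gender not in GENDERS:
        raise DataError(f"gender must be one of {GENDERS}, got {gender!r}")
    if table is None:
        table = default_recommendation_table()
    row = table[(table["age_min"] <= age_years) & (age_years <= table["age_max"])]
    if row.empty:
        raise TableCoverageError(f"age {age_years} outside recommendation table coverage")
    row = row.iloc[0]
    if gender == "female":
        return float(row["female_kcal"])
    if gender == "male":
        return float(row["male_kcal"])
    return float(row["female_kcal"] + row["male_kcal"]) / 2.0


def household_weights(members: Sequence[HouseholdMember], table: pd.DataFrame | None = None) -> np.ndarray:
    """Recommended-energy weight (kcal) for each member, in order."""
    if len(members) == 0:
        raise DataError("household must contain at least one member")
    return np.array([recommended_energy(m.age_years, m.gender, table) for m in members])


def allocation_share(
    participant: HouseholdMember,
    other_members: Iterable[HouseholdMember] = (),
    table: pd.DataFrame | None = None,
) -> float:
    """Fraction of household purchased nutrients allocated to the participant.

    share = participant's recommended energy / sum over all members.
    Other members are forced to the unknown-gender rule regardless of the
    gender recorded on them, matching how household composition data are
    collected (ages only).
    """
    if participant.gender == "unknown":
        raise DataError("the focal participant's gender must be known (female or male)")
    others = [HouseholdMember(m.age_years, "unknown") for m in other_members]
    weights = household_weights([participant, *others], table)
    return float(weights[0] / weights.sum())


def household_shares(members: Sequence[HouseholdMember], table: pd.DataFrame | None = None) -> np.ndarray:
    """Allocation shares for every member from one weight vector.

    Each member keeps their own gender rule (own gender when known,
    female/male mean when unknown); shares sum to 1 to machine
    precision, so summing individualized vectors reproduces the
    household vector.
    """
    weights = household_weights(members, table)
    return weights / weights.sum()


def individualize(household_daily: NutrientVector, share: float) -> NutrientVector:
    """Scale a household daily estimate down to one member's share.

    The same share multiplies all six analytes, which is why relative
    (energy-adjusted) measures are identical at household and individual
    level.
    """
    if not 0 < share <= 1:
        raise DataError(f"share must be in (0, 1], got {share!r}")
    return household_daily * share
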