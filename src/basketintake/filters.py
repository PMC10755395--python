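"""Inclusion/exclusion rules, sensitivity filter, eligibility screen, subgroups.

The analysis funnel applies, in order: (1) completed FFQ present,
(2) at least one purchase in the participant's primary comparison
period, (3) FFQ daily energy below 8000 kcal (>= 8000 excluded as an
outlier — four times an adult woman's recommended intake). Every rule's
count lands in an auditable :class:`ExclusionLedger`.

A sensitivity filter additionally drops participants purchasing less
than 500 kcal/d (a quarter of an adult woman's recommended intake) on
the grounds that very low purchasing signals food sourced elsewhere,
not low intake. The 8000 boundary is inclusive; the 500 boundary is
strict (exactly 500 kcal/d is retained).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

ENERGY_OUTLIER_KCAL = 8000.0
SENSITIVITY_KCAL = 500.0

LOYALTY_BANDS = ("0-20%", "21-40%", "41-60%", "61-80%", "81-100%")

LOW_MEDIUM = "low-medium (0-60%)"
HIGH = "high (61-80%)"
VERY_HIGH = "very high (81-100%)"
LOYALTY_GROUPS = (LOW_MEDIUM, HIGH, VERY_HIGH)
HOUSEHOLD_SIZE_GROUPS = ("1", "2", "3+")


@dataclass(frozen=True)
class SubgroupLabel:
    household_size_group: str
    loyalty_group: str


@dataclass
class ExclusionLedger:
    """Ordered record of how many candidates each rule removed."""

    initial_n: int
    rules: list[tuple[str, int]] = field(default_factory=list)

    def record(self, rule: str, n_excluded: int) -> None:
        if n_excluded < 0:
            raise DataError(f"negative exclusion count for rule {rule!r}")
        self.rules.append((rule, int(n_excluded)))

    @property
    def total_excluded(self) -> int:
        return sum(n for _, n in self.rules)

    @property
    def final_n(self) -> int:
        return self.initial_n - self.total_excluded

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": r, "n_excluded": n} for r, n in self.rules]
        rows.append({"rule": "final analysis set", "n_excluded": self.final_n})
        return pd.DataFrame(rows)


def apply_exclusions(
    participants: pd.DataFrame,
    ffq: pd.DataFrame,
    estimates: pd.DataFrame,
    energy_outlier_kcal: float = ENERGY_OUTLIER_KCAL,
) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Apply the analysis-set exclusion funnel.

    ``participants`` needs a ``participant_id`` column; ``ffq`` one row
    per completed FFQ with ``participant_id`` and ``energy_kcal``
    (daily); ``estimates`` per-participant purchase summaries with
    ``participant_id`` and ``n_lines`` (in-period line count).

    Returns the retained participants (original columns) and the ledger.
    """
    ids = participants["participant_id"]
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].tolist()
        raise DataError(f"duplicate participant ids: {dupes[:5]}")
    if ffq["participant_id"].duplicated().any():
        raise DataError("multiple FFQ records for one participant")

    ledger = ExclusionLedger(initial_n=len(participants))
    current = participants

    has_ffq = current["participant_id"].isin(ffq["participant_id"])
    ledger.record("no completed FFQ", int((~has_ffq).sum()))
    current = current[has_ffq]

    n_lines = current["participant_id"].map(
        estimates.set_index("participant_id")["n_lines"]
    ).fillna(0)
    purchased = n_lines > 0
    ledger.record("no purchase in comparison period", int((~purchased).sum()))
    current = current[purchased]

    ffq_energy = current["participant_id"].map(ffq.set_index("participant_id")["energy_kcal"])
    outlier = ffq_energy >= energy_outlier_kcal
    ledger.record(f"FFQ energy >= {energy_outlier_kcal:g} kcal/d", int(outlier.sum()))
    current = current[~outlier]

    assert ledger.final_n == len(current)
    return current.reset_index(drop=True), ledger


def sensitivity_filter(
    analysis_set: pd.DataFrame,
    estimates: pd.DataFrame,
    threshold_kcal: float = SENSITIVITY_KCAL,
    level: str = "household",
    shares: pd.Series | None = None,
) -> tuple[pd.DataFrame, int]:
    """Drop participants purchasing less than ``threshold_kcal``/d.

    Strict inequality: exactly the threshold is retained. ``level``
    selects whether the rule applies to household-level purchased
    energy (default) or to the allocated individual level, in which
    case per-participant ``shares`` must be given.
    """
    if not threshold_kcal > 0:
        raise ConfigurationError(f"sensitivity threshold must be > 0, got {threshold_kcal}")
    if level not in ("household", "individual"):
        raise ConfigurationError(f"level must be 'household' or 'individual', got {level!r}")
    energy = analysis_set["participant_id"].map(
        estimates.set_index("participant_id")["energy_kcal"]
    )
    if level == "individual":
        if shares is None:
            raise ConfigurationError("individual-level sensitivity filter requires shares")
        energy = energy * analysis_set["participant_id"].map(shares)
    keep = ~(energy < threshold_kcal)
    return analysis_set[keep].reset_index(drop=True), int((~keep).sum())


def household_size_group(size: int) -> str:
    if size < 1:
        raise DataError(f"household size must be >= 1, got {size}")
    return "1" if size == 1 else "2" if size == 2 else "3+"


def loyalty_group(band: str) -> str:
    band = band.strip()
    if band in ("0-20%", "21-40%", "41-60%"):
        return LOW_MEDIUM
    if band == "61-80%":
        return HIGH
    if band == "81-100%":
        return VERY_HIGH
    raise DataError(f"unrecognized loyalty band {band!r}; expected one of {LOYALTY_BANDS}")


def assign_subgroups(household_size: int, loyalty_band: str) -> SubgroupLabel:
    """Collapse household size to 1/2/3+ and loyalty bands to three groups."""
    return SubgroupLabel(household_size_group(household_size), loyalty_group(loyalty_band))


def assign_subgroups_frame(participants: pd.DataFrame) -> pd.DataFrame:
    """Vectorised subgroup columns from household_size and loyalty_band."""
    out = participants.copy()
    out["household_size_group"] = [household_size_group(s) for s in out["household_size"]]
    out["loyalty_group"] = [loyalty_group(b) for b in out["loyalty_band"]]
    return out


@dataclass(frozen=True)
class SpendReference:
    """Reference annual-spend distribution for the eligibility screen.

    ``q1``/``q3`` come from an external published distribution (e.g. a
    national family food survey); the upper cut-off is Q3 + 1.5 * IQR.
    The matching lower-tail exclusion is stated as a proportion, not a
    value, so the lower bound is supplied directly as the reference
    distribution's corresponding lower quantile value.
    """

    q1: float
    q3: float
    lower_bound: float = 0.0

    def __post_init__(self) -> None:
        if self.q3 < self.q1:
            raise ConfigurationError("spend reference: q3 < q1")

    @property
    def upper_bound(self) -> float:
        return self.q3 + 1.5 * (self.q3 - self.q1)


def eligibility_screen(
    history: pd.DataFrame,
    min_categories: int = 7,
    min_occasions: int = 10,
    spend_reference: SpendReference | None = None,
) -> bool:
    """Primary-shopper screen over one calendar year of purchase history.

    ``history`` holds one row per purchased line with columns
    ``transaction_id``, ``category`` and ``cost``. Eligible iff the
    customer shopped in at least ``min_categories`` of the 15 food
    categories, on at least ``min_occasions`` distinct occasions
    (transactions), and — when a spend reference is configured — their
    annual spend lies within [lower bound, Q3 + 1.5 * IQR].
    """
    if history.empty:
        return False
    n_categories = history["category"].nunique()
    n_occasions = history["transaction_id"].nunique()
    if n_categories < min_categories or n_occasions < min_occasions:
        return False
    if spend_reference is not None:
        spend = float(history["cost"].sum())
        if spend > spend_reference.upper_bound or spend < spend_reference.lower_bound:
            return False
    return True
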