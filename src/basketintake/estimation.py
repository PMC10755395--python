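"""Nutrient estimation from transaction lines.

Each purchased line is resolved to a total nutrient vector by linking
its product id to a per-100 g/ml back-of-pack profile; volumes are
converted with the 1 ml = 1 g approximation (no specific-gravity
table). Products without a usable profile (absent, or blank/all-zero)
fall back to a generic per-category profile, giving a 100 % match rate
after imputation. Totals over a primary comparison period are divided
by the inclusive day count to give mean daily household estimates.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, InsufficientDataError, UnknownProductError
from .nutrients import NUTRIENT_FIELDS, NutrientVector

N_CATEGORIES = 15
PACK_UNITS = ("g", "ml", "each")


@dataclass(frozen=True)
class ProductRecord:
    """A catalogue product with an optional per-100 g/ml nutrient profile."""

    product_id: str
    description: str
    category: int
    pack_amount: float
    pack_unit: str
    unit_net_weight_g: float | None = None
    per100: NutrientVector | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.category <= N_CATEGORIES:
            raise DataError(f"category must be 1-{N_CATEGORIES}, got {self.category}")
        if not self.pack_amount > 0:
            raise DataError(f"pack_amount must be > 0, got {self.pack_amount}")
        if self.pack_unit not in PACK_UNITS:
            raise DataError(f"pack_unit must be one of {PACK_UNITS}, got {self.pack_unit!r}")
        if self.pack_unit == "each" and not (self.unit_net_weight_g and self.unit_net_weight_g > 0):
            raise DataError(
                f"product {self.product_id}: pack_unit='each' requires unit_net_weight_g > 0"
            )

    @property
    def has_profile(self) -> bool:
        """True when a usable (present, not all-zero) per-100 profile exists."""
        return self.per100 is not None and any(v > 0 for v in self.per100.as_tuple())


@dataclass(frozen=True)
class GenericFoodEntry:
    """Category-level fallback profile used when a product has no label data."""

    category: int
    per100: NutrientVector

    def __post_init__(self) -> None:
        if not 1 <= self.category <= N_CATEGORIES:
            raise DataError(f"category must be 1-{N_CATEGORIES}, got {self.category}")


@dataclass(frozen=True)
class TransactionLine:
    """One purchased product line from an EPOS extract."""

    customer_id: str
    transaction_id: str
    date: dt.date
    product_id: str
    quantity: float
    cost: float = 0.0

    def __post_init__(self) -> None:
        if not self.quantity > 0:
            raise DataError(f"quantity must be > 0, got {self.quantity}")
        if self.cost < 0:
            raise DataError(f"cost must be >= 0, got {self.cost}")


@dataclass(frozen=True)
class ResolvedNutrients:
    """Total nutrients for one line plus the provenance of the profile used."""

    line: TransactionLine
    nutrients: NutrientVector
    provenance: str  # "retailer" | "generic"


@dataclass(frozen=True)
class ComparisonPeriod:
    """Closed date interval [start, end]; n_days counts both endpoints."""

    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise DataError(f"period end {self.end} precedes start {self.start}")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def contains(self, date: dt.date) -> bool:
        return self.start <= date <= self.end

    @classmethod
    def from_days(cls, start: dt.date, n_days: int) -> "ComparisonPeriod":
        if n_days < 1:
            raise ConfigurationError(f"n_days must be >= 1, got {n_days}")
        return cls(start, start + dt.timedelta(days=n_days - 1))


def _generics_map(generics: Iterable[GenericFoodEntry]) -> dict[int, GenericFoodEntry]:
    gmap = {g.category: g for g in generics}
    missing = sorted(set(range(1, N_CATEGORIES + 1)) - set(gmap))
    if missing:
        raise ConfigurationError(f"generic table missing categories {missing}")
    return gmap


def line_grams(line: TransactionLine, product: ProductRecord) -> float:
    """Total grams (ml treated as g) purchased on a line."""
    if product.pack_unit == "each":
        return line.quantity * product.unit_net_weight_g
    return line.quantity * product.pack_amount


def resolve_line(
    line: TransactionLine,
    catalogue: Mapping[str, ProductRecord],
    generics: Iterable[GenericFoodEntry],
) -> ResolvedNutrients:
    """Resolve one transaction line to its total nutrient vector.

    Uses the product's retailer per-100 profile when usable, otherwise
    the generic profile for its category (provenance ``"generic"``).
    """
    product = catalogue.get(line.product_id)
    if product is None:
        raise UnknownProductError(f"product id {line.product_id!r} not found in catalogue")
    gmap = _generics_map(generics)
    if product.has_profile:
        per100, provenance = product.per100, "retailer"
    else:
        per100, provenance = gmap[product.category].per100, "generic"
    grams = line_grams(line, product)
    return ResolvedNutrients(line=line, nutrients=per100 * (grams / 100.0), provenance=provenance)


def match_rate(
    lines: Sequence[TransactionLine],
    catalogue: Mapping[str, ProductRecord],
    generics: Iterable[GenericFoodEntry] | None = None,
) -> tuple[float, float]:
    """(pre-imputation, post-imputation) match rates over distinct products.

    Pre: fraction of distinct purchased products carrying a usable
    retailer profile. Post: 1.0 whenever the generic table covers all
    categories (it must), i.e. after imputation every line resolves.
    """
    if len(lines) == 0:
        raise InsufficientDataError("match rate undefined for an empty set of lines")
    product_ids = {ln.product_id for ln in lines}
    unknown = sorted(pid for pid in product_ids if pid not in catalogue)
    if unknown:
        raise UnknownProductError(f"product ids not in catalogue: {unknown[:5]}")
    matched = sum(1 for pid in product_ids if catalogue[pid].has_profile)
    pre = matched / len(product_ids)
    if generics is not None:
        _generics_map(generics)  # raises if coverage incomplete
    return pre, 1.0


def daily_household_estimate(
    resolved: Sequence[ResolvedNutrients],
    period: ComparisonPeriod,
) -> tuple[NutrientVector, bool]:
    """Mean daily household nutrients over a comparison period.

    Sums resolved lines dated inside the closed period and divides by
    the inclusive day count. Returns ``(vector, had_purchases)``; with
    no in-period lines the vector is zero and the flag False.
    """
    total = NutrientVector()
    n_in = 0
    for r in resolved:
        if period.contains(r.line.date):
            total = total + r.nutrients
            n_in += 1
    return total * (1.0 / period.n_days), n_in > 0


# ---------------------------------------------------------------------------
# Vectorised (DataFrame) layer used by the pipeline


def effective_per100_frame(catalogue_df: pd.DataFrame, generics_df: pd.DataFrame) -> pd.DataFrame:
    """Per-product effective per-100 profiles after generic imputation.

    Returns one row per product with the six per-100 columns, a
    ``provenance`` column and ``grams_per_unit`` (pack grams, with
    ml = g and 'each' items via unit net weight).
    """
    per100_cols = [f"{f}_100" for f in NUTRIENT_FIELDS]
    cat = catalogue_df.copy()
    has = cat[per100_cols].notna().all(axis=1) & (cat[per100_cols].fillna(0).sum(axis=1) > 0)
    cat["provenance"] = np.where(has, "retailer", "generic")
    gen = generics_df.set_index("category")[per100_cols]
    for c in per100_cols:
        cat[c] = np.where(has, cat[c], cat["category"].map(gen[c]))
    each = cat["pack_unit"] == "each"
    if each.any() and cat.loc[each, "unit_net_weight_g"].isna().any():
        bad = cat.loc[each & cat["unit_net_weight_g"].isna(), "product_id"].tolist()
        raise DataError(f"pack_unit='each' products missing unit_net_weight_g: {bad[:5]}")
    cat["grams_per_unit"] = np.where(each, cat["unit_net_weight_g"], cat["pack_amount"])
    return cat[["product_id", "category", "provenance", "grams_per_unit", *per100_cols]]


def resolve_frame(
    lines_df: pd.DataFrame,
    catalogue_df: pd.DataFrame,
    generics_df: pd.DataFrame,
) -> pd.DataFrame:
    """Resolve every transaction line to total nutrients (vectorised).

    Input columns: customer_id, transaction_id, date, product_id,
    quantity[, cost]. Output adds the six nutrient columns and
    ``provenance``.
    """
    eff = effective_per100_frame(catalogue_df, generics_df)
    unknown = set(lines_df["product_id"]) - set(eff["product_id"])
    if unknown:
        raise UnknownProductError(f"product ids not in catalogue: {sorted(unknown)[:5]}")
    out = lines_df.merge(eff, on="product_id", how="left", validate="many_to_one")
    grams = out["quantity"].to_numpy(float) * out["grams_per_unit"].to_numpy(float)
    for f in NUTRIENT_FIELDS:
        out[f] = out[f"{f}_100"].to_numpy(float) * grams / 100.0
    return out.drop(columns=[f"{f}_100" for f in NUTRIENT_FIELDS] + ["grams_per_unit"])


def daily_household_frame(
    resolved_df: pd.DataFrame,
    periods: Mapping[str, ComparisonPeriod],
) -> pd.DataFrame:
    """Per-customer mean daily household nutrients over each customer's period.

    ``periods`` maps customer_id -> ComparisonPeriod (participants in
    different recruitment waves have different windows). Customers with
    no in-period lines get a zero row with ``n_lines = 0``.
    """
    pframe = pd.DataFrame(
        {
            "customer_id": list(periods),
            "_start": [pd.Timestamp(p.start) for p in periods.values()],
            "_end": [pd.Timestamp(p.end) for p in periods.values()],
            "_n_days": [p.n_days for p in periods.values()],
        }
    )
    df = resolved_df[["customer_id", "date", *NUTRIENT_FIELDS]].copy()
    df["date"] = pd.to_datetime(df["date"])
    df = df.merge(pframe, on="customer_id", how="inner", validate="many_to_one")
    in_period = (df["date"] >= df["_start"]) & (df["date"] <= df["_end"])
    grouped = df[in_period].groupby("customer_id", sort=False)[list(NUTRIENT_FIELDS)].agg(["sum"])
    totals = grouped.droplevel(1, axis=1)
    counts = df[in_period].groupby("customer_id", sort=False).size()
    out = pframe.set_index("customer_id")
    for f in NUTRIENT_FIELDS:
        out[f] = totals[f].reindex(out.index).fillna(0.0) / out["_n_days"]
    out["n_lines"] = counts.reindex(out.index).fillna(0).astype(int)
    return out.reset_index().drop(columns=["_start", "_end", "_n_days"])[
        ["customer_id", "n_lines", *NUTRIENT_FIELDS]
    ]
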