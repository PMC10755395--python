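"""Transaction-line resolution, match rates and daily household estimates."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from basketintake.errors import (
    ConfigurationError,
    DataError,
    InsufficientDataError,
    UnknownProductError,
)
from basketintake.estimation import (
    ComparisonPeriod,
    GenericFoodEntry,
    ProductRecord,
    TransactionLine,
    daily_household_estimate,
    daily_household_frame,
    match_rate,
    resolve_frame,
    resolve_line,
)
from basketintake.nutrients import NUTRIENT_FIELDS, NutrientVector


def _generics():
    return [
        GenericFoodEntry(category=c, per100=NutrientVector(100 + c, 5, 3, 2, 1, 50))
        for c in range(1, 16)
    ]


@pytest.fixture
def drink():
    return ProductRecord(
        product_id="D1",
        description="fizzy drink 500ml",
        category=3,
        pack_amount=500,
        pack_unit="ml",
        per100=NutrientVector(42, 10.6, 0, 0, 0, 5),
    )


@pytest.fixture
def loose_bananas():
    # loose-weight item: pack modelled as 1000 g, quantity in packs
    return ProductRecord(
        product_id="B1",
        description="bananas loose",
        category=5,
        pack_amount=1000,
        pack_unit="g",
        per100=NutrientVector(89, 12, 1.1, 0.3, 0.1, 1),
    )


def _line(pid, qty, date=dt.date(2020, 6, 5)):
    return TransactionLine("C1", "T1", date, pid, qty, cost=1.0)


class TestResolveLine:
    def test_ml_treated_as_g(self, drink):
        """2 units of a 500 ml drink at 42 kcal/100 ml -> 420 kcal."""
        res = resolve_line(_line("D1", 2), {"D1": drink}, _generics())
        assert res.nutrients.energy_kcal == pytest.approx(420.0)
        assert res.provenance == "retailer"

    def test_generic_fallback_for_missing_profile(self):
        p = ProductRecord("X1", "bakery item", category=7, pack_amount=400, pack_unit="g")
        res = resolve_line(_line("X1", 1), {"X1": p}, _generics())
        # category-7 generic: 107 kcal/100g * 400 g
        assert res.nutrients.energy_kcal == pytest.approx(107 * 4)
        assert res.provenance == "generic"

    def test_blank_all_zero_profile_treated_as_missing(self):
        p = ProductRecord(
            "X2", "blank label", category=2, pack_amount=100, pack_unit="g",
            per100=NutrientVector(),
        )
        res = resolve_line(_line("X2", 1), {"X2": p}, _generics())
        assert res.provenance == "generic"

    def test_loose_weight_item(self, loose_bananas):
        """0.35 packs of a 1000 g pack = 3.5 x per-100 profile."""
        res = resolve_line(_line("B1", 0.35), {"B1": loose_bananas}, _generics())
        assert np.allclose(res.nutrients.as_array(), loose_bananas.per100.as_array() * 3.5)

    def test_each_unit_uses_net_weight(self):
        p = ProductRecord(
            "E1", "pie", category=4, pack_amount=1, pack_unit="each",
            unit_net_weight_g=250, per100=NutrientVector(300, 5, 6, 15, 7, 400),
        )
        res = resolve_line(_line("E1", 2), {"E1": p}, _generics())
        assert res.nutrients.energy_kcal == pytest.approx(300 * 500 / 100)

    def test_unknown_product_error_names_id(self, drink):
        with pytest.raises(UnknownProductError, match="NOPE"):
            resolve_line(_line("NOPE", 1), {"D1": drink}, _generics())

    def test_each_without_net_weight_rejected(self):
        with pytest.raises(DataError):
            ProductRecord("E2", "pie", category=4, pack_amount=1, pack_unit="each")


class TestMatchRate:
    def test_enumeration_three_of_four(self, drink, loose_bananas):
        catalogue = {
            "D1": drink,
            "B1": loose_bananas,
            "M1": ProductRecord("M1", "unmatched", 2, 100, "g"),
            "M2": ProductRecord("M2", "matched", 2, 100, "g",
                                per100=NutrientVector(50, 1, 1, 1, 0.5, 10)),
        }
        lines = [_line(pid, 1) for pid in ["D1", "B1", "M1", "M2", "D1"]]
        pre, post = match_rate(lines, catalogue, _generics())
        assert pre == pytest.approx(0.75)  # distinct products, not lines
        assert post == 1.0

    def test_all_matched(self, drink):
        pre, post = match_rate([_line("D1", 1)], {"D1": drink}, _generics())
        assert (pre, post) == (1.0, 1.0)

    def test_empty_lines_error(self, drink):
        with pytest.raises(InsufficientDataError):
            match_rate([], {"D1": drink}, _generics())


class TestDailyEstimate:
    def test_divide_by_period_days(self, drink):
        period = ComparisonPeriod.from_days(dt.date(2020, 6, 1), 91)
        assert period.n_days == 91
        # 182000 kcal over 91 days -> 2000 kcal/d
        lines = [_line("D1", 182000 / 420 * 2, dt.date(2020, 7, 1))]
        resolved = [resolve_line(ln, {"D1": drink}, _generics()) for ln in lines]
        daily, flag = daily_household_estimate(resolved, period)
        assert daily.energy_kcal == pytest.approx(2000.0)
        assert flag

    def test_two_lines_ten_days(self, drink):
        period = ComparisonPeriod.from_days(dt.date(2020, 6, 1), 10)
        qty = 500 / 210  # one 500 ml unit = 210 kcal, so this is 500 kcal per line
        lines = [_line("D1", qty, dt.date(2020, 6, 1)), _line("D1", qty, dt.date(2020, 6, 10))]
        resolved = [resolve_line(ln, {"D1": drink}, _generics()) for ln in lines]
        daily, _ = daily_household_estimate(resolved, period)
        assert daily.energy_kcal == pytest.approx(100.0)

    def test_out_of_period_lines_ignored_and_empty_flagged(self, drink):
        period = ComparisonPeriod.from_days(dt.date(2020, 6, 1), 10)
        resolved = [resolve_line(_line("D1", 5, dt.date(2020, 8, 1)), {"D1": drink}, _generics())]
        daily, flag = daily_household_estimate(resolved, period)
        assert daily.as_tuple() == (0,) * 6
        assert not flag

    def test_period_endpoints_inclusive(self, drink):
        period = ComparisonPeriod.from_days(dt.date(2020, 6, 1), 2)
        for day in [dt.date(2020, 6, 1), dt.date(2020, 6, 2)]:
            resolved = [resolve_line(_line("D1", 1, day), {"D1": drink}, _generics())]
            _, flag = daily_household_estimate(resolved, period)
            assert flag

    def test_invalid_period(self):
        with pytest.raises(ConfigurationError):
            ComparisonPeriod.from_days(dt.date(2020, 6, 1), 0)


class TestInvariants:
    def _resolved(self, drink, quantities_dates):
        return [
            resolve_line(_line("D1", q, d), {"D1": drink}, _generics())
            for q, d in quantities_dates
        ]

    def test_additivity_over_period_partition(self, drink):
        """The 20-day estimate equals the day-weighted mix of the two
        10-day sub-period estimates."""
        full = ComparisonPeriod.from_days(dt.date(2020, 6, 1), 20)
        first = ComparisonPeriod.from_days(dt.date(2020, 6, 1), 10)
        second = ComparisonPeriod.from_days(dt.date(2020, 6, 11), 10)
        resolved = self._resolved(
            drink, [(1, dt.date(2020, 6, 3)), (2, dt.date(2020, 6, 14)), (4, dt.date(2020, 6, 20))]
        )
        efull, _ = daily_household_estimate(resolved, full)
        e1, _ = daily_household_estimate(resolved, first)
        e2, _ = daily_household_estimate(resolved, second)
        mix = e1 * (10 / 20) + e2 * (10 / 20)
        assert efull.isclose(mix, rtol=1e-12)

    def test_scale_equivariance(self, drink):
        period = ComparisonPeriod.from_days(dt.date(2020, 6, 1), 7)
        base = self._resolved(drink, [(1, dt.date(2020, 6, 2)), (3, dt.date(2020, 6, 5))])
        doubled = self._resolved(drink, [(2, dt.date(2020, 6, 2)), (6, dt.date(2020, 6, 5))])
        e1, _ = daily_household_estimate(base, period)
        e2, _ = daily_household_estimate(doubled, period)
        assert e2.isclose(e1 * 2, rtol=1e-12)

    def test_provenance_partition(self, small_dataset):
        resolved = resolve_frame(
            small_dataset.transactions, small_dataset.catalogue_df, small_dataset.generics_df
        )
        counts = resolved["provenance"].value_counts()
        assert counts.get("retailer", 0) + counts.get("generic", 0) == len(small_dataset.transactions)


class TestFrameLayer:
    def test_frame_resolution_matches_scalar(self, small_dataset):
        """Vectorised resolution agrees with the per-line scalar API."""
        catalogue = {p.product_id: p for p in small_dataset.products}
        sub = small_dataset.transactions.head(25)
        frame = resolve_frame(sub, small_dataset.catalogue_df, small_dataset.generics_df)
        for i, row in sub.iterrows():
            line = TransactionLine(
                row["customer_id"], row["transaction_id"], row["date"],
                row["product_id"], row["quantity"], row["cost"],
            )
            res = resolve_line(line, catalogue, small_dataset.generics)
            assert np.allclose(
                frame.loc[i, list(NUTRIENT_FIELDS)].to_numpy(float),
                res.nutrients.as_array(),
                rtol=1e-12,
            )
            assert frame.loc[i, "provenance"] == res.provenance

    def test_daily_frame_zero_row_for_absent_customer(self, small_dataset):
        period = ComparisonPeriod.from_days(dt.date(2020, 6, 1), 10)
        resolved = resolve_frame(
            small_dataset.transactions, small_dataset.catalogue_df, small_dataset.generics_df
        )
        out = daily_household_frame(resolved, {"GHOST": period})
        assert out.loc[0, "n_lines"] == 0
        assert out.loc[0, "energy_kcal"] == 0.0
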