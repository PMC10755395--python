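"""Synthetic cohort, catalogue, transaction and FFQ generator.

Real loyalty-card transaction extracts and FFQ-derived intakes are
confidential, so every pipeline input is generated here with a known
ground-truth agreement structure:

* A product catalogue with back-of-pack per-100 g/ml profiles, a
  configurable fraction of which are absent (missing label data), plus
  a 15-category generic fallback table.
* A cohort of adult participants (age, gender, household members with
  unknown genders, five self-reported loyalty bands, recruitment wave
  with pilot), each observed over a ~3-month primary comparison period
  inside a study year preceded by a baseline year.
* Transactions whose comparison-period totals are constructed so that,
  after resolution through the catalogue, conversion to mean daily
  household estimates and energy-recommendation allocation down to the
  participant, the log-scale purchase:intake relationship is exactly
  d = b0 + b1 * m + Normal(0, sigma), with d = ln(individual purchase
  energy) - ln(FFQ intake energy) and m the mean of the two logs.

The mean-of-logs m is drawn exogenously per participant and the
difference d is generated from it, so downstream OLS of d on m is a
consistent estimator of (b0, b1) — the property the recovery tests
exercise. Purchases and intake follow as exp(m +/- d/2). True intake
is FFQ / (1 - underreport_fraction); the ground-truth retailer share
is the waste-discounted purchase over true intake. Waste and
under-reporting therefore live in the ground-truth bookkeeping; the
observed purchase:FFQ relationship is exactly the configured one.

One fixed RNG stream per output family (catalogue / cohort /
transactions) keeps e.g. the catalogue invariant under changes to
n_participants.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy.optimize import nnls

from . import allocation
from .errors import ConfigurationError, DataError
from .estimation import ComparisonPeriod, GenericFoodEntry, N_CATEGORIES, ProductRecord
from .filters import LOYALTY_BANDS
from .nutrients import NUTRIENT_FIELDS, NutrientVector

_STREAM_CATALOGUE, _STREAM_COHORT, _STREAM_TRANSACTIONS = 0, 1, 2

PER100_COLS = [f"{f}_100" for f in NUTRIENT_FIELDS]


class WaveSpec(BaseModel):
    """One recruitment wave: a study year containing a comparison window."""

    model_config = ConfigDict(frozen=True)

    label: str
    study_start: dt.date
    comparison_start: dt.date


def default_wave_scheme() -> list[WaveSpec]:
    """A pilot plus four seasonal waves across one study year."""
    starts = {
        "pilot": dt.date(2020, 2, 3),
        "wave1": dt.date(2020, 6, 1),
        "wave2": dt.date(2020, 9, 7),
        "wave3": dt.date(2020, 12, 7),
        "wave4": dt.date(2021, 3, 1),
    }
    return [WaveSpec(label=k, study_start=v, comparison_start=v) for k, v in starts.items()]


class GeneratorConfig(BaseModel):
    """All knobs of the synthetic world.

    The ratio structure defaults reproduce the printed individual-level
    energy agreement summary at A = 2000 kcal (ratio ~0.86 with LoA
    ~0.22-3.43): b0 = 1.75, b1 = -0.25, sigma = 0.70. Cohort marginals
    default to the published sample description (72 % female, age
    ~N(56, 13), mean household size ~2.2, 82 %/64 % above the 40 %/60 %
    loyalty thresholds). Basket/trip intensities are placeholders — no
    basket model is published — and only period totals matter
    downstream.
    """

    model_config = ConfigDict(frozen=True)

    seed: int = Field(0, ge=0, lt=2**31)
    n_participants: int = Field(686, ge=1)
    wave_scheme: list[WaveSpec] = Field(default_factory=default_wave_scheme)
    comparison_days: int = Field(91, ge=1)
    catalogue_size: int = Field(120, ge=15)
    missing_profile_rate: float = Field(0.28, ge=0.0, le=1.0)
    household_size_distribution: dict[int, float] = Field(
        default_factory=lambda: {1: 0.25, 2: 0.45, 3: 0.15, 4: 0.10, 5: 0.05}
    )
    loyalty_band_distribution: dict[str, float] = Field(
        default_factory=lambda: {
            "0-20%": 0.08,
            "21-40%": 0.10,
            "41-60%": 0.18,
            "61-80%": 0.30,
            "81-100%": 0.34,
        }
    )
    ratio_intercept: float = 1.75
    ratio_slope: float = -0.25
    ratio_noise_sd: float = Field(0.70, ge=0.0)
    waste_fraction: float = Field(0.10, ge=0.0, lt=1.0)
    underreport_fraction: float = Field(0.10, ge=0.0, lt=1.0)
    nutrient_profile_noise_sd: float = Field(0.15, ge=0.0)
    mean_log_center: float = math.log(2000.0)
    mean_log_sd: float = Field(0.25, ge=0.0)
    trips_per_week: float = Field(1.5, gt=0.0)
    out_of_period_trips_per_week: float = Field(0.7, ge=0.0)
    lines_per_trip: float = Field(5.0, ge=1.0)

    @field_validator("ratio_slope")
    @classmethod
    def _slope_not_two(cls, v: float) -> float:
        if v == 2.0:
            raise ValueError("ratio_slope: the value 2 makes the log relationship degenerate")
        return v

    @field_validator("household_size_distribution")
    @classmethod
    def _hh_dist(cls, v: dict[int, float]) -> dict[int, float]:
        if not set(v) <= {1, 2, 3, 4, 5}:
            raise ValueError("household_size_distribution: sizes must be in {1,...,5}")
        if any(p < 0 for p in v.values()) or abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("household_size_distribution: probabilities must be >= 0 and sum to 1")
        return v

    @field_validator("loyalty_band_distribution")
    @classmethod
    def _loyalty_dist(cls, v: dict[str, float]) -> dict[str, float]:
        if not set(v) <= set(LOYALTY_BANDS):
            raise ValueError(f"loyalty_band_distribution: bands must be among {LOYALTY_BANDS}")
        if any(p < 0 for p in v.values()) or abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("loyalty_band_distribution: probabilities must be >= 0 and sum to 1")
        return v

    @model_validator(mode="after")
    def _waves_valid(self) -> "GeneratorConfig":
        if not self.wave_scheme:
            raise ValueError("wave_scheme: at least one wave is required")
        for w in self.wave_scheme:
            if not (w.study_start <= w.comparison_start):
                raise ValueError(f"wave_scheme: wave {w.label} comparison starts before study year")
            end = w.comparison_start + dt.timedelta(days=self.comparison_days - 1)
            if end >= w.study_start + dt.timedelta(days=365):
                raise ValueError(
                    f"wave_scheme: wave {w.label} comparison period leaves the study year"
                )
        return self

    # convenience ---------------------------------------------------------

    def wave(self, label: str) -> WaveSpec:
        for w in self.wave_scheme:
            if w.label == label:
                return w
        raise ConfigurationError(f"unknown wave label {label!r}")

    def comparison_period(self, wave_label: str) -> ComparisonPeriod:
        w = self.wave(wave_label)
        return ComparisonPeriod.from_days(w.comparison_start, self.comparison_days)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def identity_config(n_participants: int = 150, seed: int = 0, **overrides) -> GeneratorConfig:
    """Perfect-agreement world: purchases equal intake for everyone.

    sigma = b0 = b1 = 0 with no waste, no under-reporting, no
    nutrient-profile jitter and single-person households (so household
    and individual purchase levels coincide with intake).
    """
    params = dict(
        seed=seed,
        n_participants=n_participants,
        ratio_intercept=0.0,
        ratio_slope=0.0,
        ratio_noise_sd=0.0,
        waste_fraction=0.0,
        underreport_fraction=0.0,
        nutrient_profile_noise_sd=0.0,
        household_size_distribution={1: 1.0},
    )
    params.update(overrides)
    return GeneratorConfig(**params)


def load_config(path) -> GeneratorConfig:
    """Read a GeneratorConfig from a YAML (or JSON) file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return GeneratorConfig(**raw)
    except Exception as exc:  # pydantic names the offending field
        raise ConfigurationError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Participants and ground truth


@dataclass(frozen=True)
class Participant:
    participant_id: str
    customer_id: str
    age_years: int
    gender: str
    loyalty_band: str
    wave: str
    other_members: tuple[allocation.HouseholdMember, ...] = ()

    @property
    def household_size(self) -> int:
        return 1 + len(self.other_members)

    def as_member(self) -> allocation.HouseholdMember:
        return allocation.HouseholdMember(self.age_years, self.gender)


@dataclass(frozen=True)
class ParticipantTruth:
    """Per-participant generating quantities (tests only, never pipeline input)."""

    mean_log: float
    log_diff: float
    share: float
    true_retailer_share: float
    true_intake: NutrientVector
    ffq_intake: NutrientVector
    purchase_individual: NutrientVector


@dataclass
class GroundTruth:
    ratio_intercept: float
    ratio_slope: float
    ratio_noise_sd: float
    per_participant: dict[str, ParticipantTruth] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Catalogue

#: Seven deterministic staple products spanning the nutrient cone so any
#: realistic target vector is exactly representable by a non-negative
#: product combination: (description, per-100 profile).
_STAPLES: list[tuple[str, NutrientVector]] = [
    ("sunflower oil", NutrientVector(900, 0, 0, 100, 11, 0)),
    ("butter", NutrientVector(740, 0.6, 0.6, 82, 52, 600)),
    ("double cream", NutrientVector(330, 3, 2, 34, 29, 40)),
    ("granulated sugar", NutrientVector(400, 100, 0, 0, 0, 0)),
    ("protein powder", NutrientVector(370, 2, 90, 1.5, 0.5, 150)),
    ("table salt", NutrientVector(0, 0, 0, 0, 0, 38758)),
    ("cornflour", NutrientVector(360, 0.3, 0.6, 0.2, 0.05, 10)),
]


def _random_per100(rng: np.random.Generator) -> NutrientVector:
    energy = float(rng.uniform(30, 550))
    # energy shares of fat / sugars / protein, leaving room for other carbs
    shares = rng.dirichlet([2.0, 2.0, 2.0, 3.0]) * 0.95
    fat = shares[0] * energy / 9.0
    sugars = shares[1] * energy / 3.9
    protein = shares[2] * energy / 4.0
    satfat = float(rng.uniform(0.1, 0.8)) * fat
    sodium = float(rng.uniform(0, 800))
    return NutrientVector(energy, sugars, protein, fat, satfat, sodium)


def generate_catalogue(
    config: GeneratorConfig,
) -> tuple[list[ProductRecord], list[GenericFoodEntry]]:
    """Catalogue with controlled profile missingness plus the generic table.

    Exactly ``round(missing_profile_rate * catalogue_size)`` products
    carry no per-100 profile; the generic table covers all 15
    categories (entries for the staple categories mirror the staple
    profiles, so imputation of a missing staple is exact).
    """
    rng = config.rng(_STREAM_CATALOGUE)
    products: list[ProductRecord] = []
    per100s: list[NutrientVector] = []
    for i in range(config.catalogue_size):
        if i < len(_STAPLES):
            desc, per100 = _STAPLES[i]
            category = i + 1
            pack_unit, pack_amount, unit_w = "g", float(rng.choice([250, 500, 1000])), None
        else:
            desc = f"product {i:04d}"
            category = int(rng.integers(1, N_CATEGORIES + 1))
            per100 = _random_per100(rng)
            pack_unit = str(rng.choice(["g", "ml", "each"], p=[0.6, 0.25, 0.15]))
            pack_amount = float(rng.choice([100, 150, 250, 330, 400, 500, 750, 1000]))
            unit_w = float(rng.uniform(30, 500)) if pack_unit == "each" else None
            if pack_unit == "each":
                pack_amount = 1.0
        products.append(
            ProductRecord(
                product_id=f"SKU{i:05d}",
                description=desc,
                category=category,
                pack_amount=pack_amount,
                pack_unit=pack_unit,
                unit_net_weight_g=unit_w,
                per100=per100,
            )
        )
        per100s.append(per100)

    n_missing = round(config.missing_profile_rate * config.catalogue_size)
    missing_idx = set(rng.choice(config.catalogue_size, size=n_missing, replace=False).tolist())
    products = [
        ProductRecord(
            product_id=p.product_id,
            description=p.description,
            category=p.category,
            pack_amount=p.pack_amount,
            pack_unit=p.pack_unit,
            unit_net_weight_g=p.unit_net_weight_g,
            per100=None if i in missing_idx else p.per100,
        )
        for i, p in enumerate(products)
    ]

    generics = []
    for c in range(1, N_CATEGORIES + 1):
        if c <= len(_STAPLES):
            generics.append(GenericFoodEntry(category=c, per100=_STAPLES[c - 1][1]))
        else:
            generics.append(GenericFoodEntry(category=c, per100=_random_per100(rng)))
    return products, generics


def catalogue_frame(products: Sequence[ProductRecord]) -> pd.DataFrame:
    rows = []
    for p in products:
        per100 = p.per100.as_tuple() if p.per100 is not None else [np.nan] * len(NUTRIENT_FIELDS)
        rows.append(
            {
                "product_id": p.product_id,
                "description": p.description,
                "category": p.category,
                "pack_amount": p.pack_amount,
                "pack_unit": p.pack_unit,
                "unit_net_weight_g": p.unit_net_weight_g if p.unit_net_weight_g else np.nan,
                **dict(zip(PER100_COLS, per100)),
            }
        )
    return pd.DataFrame(rows)


def generics_frame(generics: Sequence[GenericFoodEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"category": g.category, **dict(zip(PER100_COLS, g.per100.as_tuple()))}
            for g in generics
        ]
    )


# ---------------------------------------------------------------------------
# Cohort


def _draw_ffq_vector(rng: np.random.Generator, energy_kcal: float) -> NutrientVector:
    """A plausible daily intake vector at a given energy."""
    sugars_pct = float(np.clip(rng.normal(20, 3), 8, 35))
    protein_pct = float(np.clip(rng.normal(16, 2), 10, 25))
    fat_pct = float(np.clip(rng.normal(34, 4), 20, 48))
    total = sugars_pct + protein_pct + fat_pct
    if total > 93:
        sugars_pct, protein_pct, fat_pct = (
            x * 93 / total for x in (sugars_pct, protein_pct, fat_pct)
        )
    satfat_ratio = float(np.clip(rng.normal(0.38, 0.05), 0.20, 0.60))
    na_density = float(np.clip(rng.normal(1.2, 0.15), 0.7, 1.8))
    fat = fat_pct / 100 * energy_kcal / 9.0
    return NutrientVector(
        energy_kcal=energy_kcal,
        sugars_g=sugars_pct / 100 * energy_kcal / 3.9,
        protein_g=protein_pct / 100 * energy_kcal / 4.0,
        fat_g=fat,
        satfat_g=satfat_ratio * fat,
        sodium_mg=na_density * energy_kcal,
    )


def _purchase_vector(
    rng: np.random.Generator, ffq: NutrientVector, purchase_energy: float, jitter_sd: float
) -> NutrientVector:
    """Purchased individual-level vector: FFQ per-kcal profile with jitter.

    The purchased basket's composition tracks the diet's composition up
    to per-nutrient log-normal noise; macro energy is capped at 93 % of
    total energy so the vector stays representable by real foods.
    """
    scale = purchase_energy / ffq.energy_kcal
    jitter = np.exp(rng.normal(0.0, jitter_sd, size=4)) if jitter_sd > 0 else np.ones(4)
    sugars = ffq.sugars_g * scale * jitter[0]
    protein = ffq.protein_g * scale * jitter[1]
    fat = ffq.fat_g * scale * jitter[2]
    satfat_ratio = ffq.satfat_g / ffq.fat_g * jitter[3] if ffq.fat_g > 0 else 0.0
    satfat = float(np.clip(satfat_ratio, 0.12, 0.85)) * fat if fat > 0 else 0.0
    sodium = ffq.sodium_mg * scale * (float(np.exp(rng.normal(0.0, jitter_sd))) if jitter_sd > 0 else 1.0)
    macro_e = 3.9 * sugars + 4.0 * protein + 9.0 * fat
    if macro_e > 0.93 * purchase_energy:
        f = 0.93 * purchase_energy / macro_e
        sugars, protein, fat, satfat = sugars * f, protein * f, fat * f, satfat * f
    return NutrientVector(purchase_energy, sugars, protein, fat, satfat, sodium)


def generate_cohort(config: GeneratorConfig) -> tuple[list[Participant], GroundTruth]:
    """Participants plus the generating quantities for each of them.

    All per-participant scalars — demographics, household, wave, the
    exogenous mean-of-logs m, the log difference d, intake and purchase
    vectors and the allocation share — are drawn here in the cohort
    stream so the transaction builder is a deterministic function of
    the truth (plus its own basket-level stream).
    """
    rng = config.rng(_STREAM_COHORT)
    table = allocation.default_recommendation_table()
    sizes = sorted(config.household_size_distribution)
    size_p = np.array([config.household_size_distribution[s] for s in sizes])
    bands = [b for b in LOYALTY_BANDS if b in config.loyalty_band_distribution]
    band_p = np.array([config.loyalty_band_distribution[b] for b in bands])
    wave_labels = [w.label for w in config.wave_scheme]

    participants: list[Participant] = []
    truth = GroundTruth(
        ratio_intercept=config.ratio_intercept,
        ratio_slope=config.ratio_slope,
        ratio_noise_sd=config.ratio_noise_sd,
    )
    one_minus_u = 1.0 - config.underreport_fraction
    for i in range(config.n_participants):
        pid = f"P{i:05d}"
        age = int(np.clip(round(rng.normal(56.2, 12.9)), 18, 90))
        gender = "female" if rng.random() < 0.72 else "male"
        size = int(rng.choice(sizes, p=size_p))
        others = []
        for _ in range(size - 1):
            if rng.random() < 0.6:
                other_age = int(np.clip(round(age + rng.normal(0, 6)), 18, 90))
            else:
                other_age = int(rng.integers(0, 18))
            others.append(allocation.HouseholdMember(other_age, "unknown"))
        participant = Participant(
            participant_id=pid,
            customer_id=f"C{i:05d}",
            age_years=age,
            gender=gender,
            loyalty_band=str(rng.choice(bands, p=band_p)),
            wave=str(rng.choice(wave_labels)),
            other_members=tuple(others),
        )
        participants.append(participant)

        m = rng.normal(config.mean_log_center, config.mean_log_sd)
        eps = rng.normal(0.0, config.ratio_noise_sd) if config.ratio_noise_sd > 0 else 0.0
        d = config.ratio_intercept + config.ratio_slope * m + eps
        intake_energy = math.exp(m - d / 2.0)
        purchase_energy = math.exp(m + d / 2.0)
        ffq = _draw_ffq_vector(rng, intake_energy)
        true_intake = ffq * (1.0 / one_minus_u)
        purchase = _purchase_vector(
            rng, ffq, purchase_energy, config.nutrient_profile_noise_sd
        )
        share = allocation.allocation_share(participant.as_member(), others, table)
        true_share = float(
            np.clip(purchase_energy * (1.0 - config.waste_fraction) / true_intake.energy_kcal, 0, 1)
        )
        truth.per_participant[pid] = ParticipantTruth(
            mean_log=float(m),
            log_diff=float(d),
            share=share,
            true_retailer_share=true_share,
            true_intake=true_intake,
            ffq_intake=ffq,
            purchase_individual=purchase,
        )
    return participants, truth


def participants_frame(participants: Sequence[Participant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": p.participant_id,
                "customer_id": p.customer_id,
                "age_years": p.age_years,
                "gender": p.gender,
                "household_size": p.household_size,
                "loyalty_band": p.loyalty_band,
                "wave": p.wave,
            }
            for p in participants
        ]
    )


def members_frame(participants: Sequence[Participant]) -> pd.DataFrame:
    rows = []
    for p in participants:
        for j, m in enumerate(p.other_members):
            rows.append(
                {
                    "participant_id": p.participant_id,
                    "member_index": j,
                    "age_years": m.age_years,
                    "gender": m.gender,
                }
            )
    return pd.DataFrame(rows, columns=["participant_id", "member_index", "age_years", "gender"])


def ffq_frame(participants: Sequence[Participant], truth: GroundTruth) -> pd.DataFrame:
    rows = []
    for p in participants:
        t = truth.per_participant[p.participant_id]
        rows.append(
            {"participant_id": p.participant_id, **dict(zip(NUTRIENT_FIELDS, t.ffq_intake.as_tuple()))}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Transactions


def _effective_unit_vectors(
    products: Sequence[ProductRecord], generics: Sequence[GenericFoodEntry]
) -> dict[str, np.ndarray]:
    """Per-unit (one pack / one item) nutrient vector after imputation."""
    gmap = {g.category: g.per100 for g in generics}
    out = {}
    for p in products:
        per100 = p.per100 if p.has_profile else gmap[p.category]
        grams = p.unit_net_weight_g if p.pack_unit == "each" else p.pack_amount
        out[p.product_id] = per100.as_array() * (grams / 100.0)
    return out


def _solve_basket(
    target: np.ndarray, product_ids: list[str], unit_vectors: dict[str, np.ndarray]
) -> dict[str, float]:
    """Non-negative product quantities whose resolved total equals target.

    Solved by NNLS on scale-normalised rows; the staples guarantee the
    target lies in the cone, so the residual is numerically zero.
    """
    A = np.column_stack([unit_vectors[pid] for pid in product_ids])
    row_scale = np.where(target > 0, target, 1.0)
    q, _ = nnls(A / row_scale[:, None], np.where(target > 0, 1.0, 0.0))
    achieved = A @ q
    rel_resid = np.max(np.abs(achieved - target) / row_scale)
    if rel_resid > 1e-6:
        raise DataError(f"basket construction residual {rel_resid:.2e}; target not representable")
    return {pid: float(qi) for pid, qi in zip(product_ids, q) if qi > 1e-12}


def generate_observations(
    config: GeneratorConfig,
    participants: Sequence[Participant],
    catalogue: tuple[Sequence[ProductRecord], Sequence[GenericFoodEntry]],
    truth: GroundTruth,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Transaction lines and FFQ records for a generated cohort.

    Comparison-period baskets are solved so the period total equals the
    participant's household target exactly (individual purchase target
    divided by their allocation share, times the day count); quantities
    are then spread over Poisson-distributed shopping trips. Baseline-
    year and remaining study-year trips are free noise — they never
    enter the primary comparison window.

    Returns ``(transactions, ffq)`` DataFrames in the documented CSV
    schemas (one row per purchased line / one row per participant).
    """
    products, generics = catalogue
    if not products:
        raise ConfigurationError("catalogue: must contain at least one product")
    rng = config.rng(_STREAM_TRANSACTIONS)
    unit_vectors = _effective_unit_vectors(products, generics)
    staple_ids = [p.product_id for p in products[: len(_STAPLES)]]
    other_ids = [p.product_id for p in products[len(_STAPLES):]]

    cols: dict[str, list] = {
        "customer_id": [],
        "transaction_id": [],
        "date": [],
        "product_id": [],
        "quantity": [],
        "cost": [],
    }

    def emit(cust, tid, date, pid, qty, cost):
        cols["customer_id"].append(cust)
        cols["transaction_id"].append(tid)
        cols["date"].append(date)
        cols["product_id"].append(pid)
        cols["quantity"].append(qty)
        cols["cost"].append(cost)

    for participant in participants:
        t = truth.per_participant[participant.participant_id]
        period = config.comparison_period(participant.wave)
        target = t.purchase_individual.as_array() / t.share * period.n_days

        n_extra = min(len(other_ids), 12)
        extra = (
            [other_ids[k] for k in rng.choice(len(other_ids), size=n_extra, replace=False)]
            if n_extra
            else []
        )
        quantities = _solve_basket(target, staple_ids + extra, unit_vectors)

        n_trips = max(1, int(rng.poisson(config.trips_per_week * period.n_days / 7.0)))
        trip_offsets = np.sort(rng.integers(0, period.n_days, size=n_trips))
        trip_dates = [period.start + dt.timedelta(days=int(o)) for o in trip_offsets]
        tcount = 0
        for pid, qty in quantities.items():
            k = int(min(n_trips, rng.integers(1, 4)))
            trip_idx = rng.choice(n_trips, size=k, replace=False)
            weights = rng.dirichlet(np.ones(k)) if k > 1 else np.array([1.0])
            for ti, w in zip(trip_idx, weights):
                q = qty * float(w)
                if q <= 0:
                    continue
                emit(
                    participant.customer_id,
                    f"{participant.customer_id}-T{int(ti):04d}",
                    trip_dates[int(ti)],
                    pid,
                    q,
                    round(q * float(rng.uniform(0.5, 6.0)), 2),
                )
            tcount += 1

        # out-of-period noise: baseline year plus the study year outside the window
        wave = config.wave(participant.wave)
        baseline_start = wave.study_start - dt.timedelta(days=365)
        out_days = []
        for offset in range(730):
            day = baseline_start + dt.timedelta(days=offset)
            if not period.contains(day):
                out_days.append(day)
        n_out = int(rng.poisson(config.out_of_period_trips_per_week * len(out_days) / 7.0))
        if n_out > 0 and out_days:
            day_idx = rng.integers(0, len(out_days), size=n_out)
            for j, di in enumerate(day_idx):
                n_lines = 1 + int(rng.poisson(max(config.lines_per_trip - 1, 0)))
                pids = rng.choice(len(products), size=n_lines)
                qs = np.exp(rng.normal(0.0, 0.5, size=n_lines))
                for pi, q in zip(pids, qs):
                    emit(
                        participant.customer_id,
                        f"{participant.customer_id}-B{j:04d}",
                        out_days[int(di)],
                        products[int(pi)].product_id,
                        float(q),
                        round(float(q) * float(rng.uniform(0.5, 6.0)), 2),
                    )

    transactions = pd.DataFrame(cols)
    return transactions, ffq_frame(participants, truth)


# ---------------------------------------------------------------------------
# Bundled dataset


@dataclass
class Dataset:
    """Everything one pipeline run consumes, plus the ground truth."""

    config: GeneratorConfig
    products: list[ProductRecord]
    generics: list[GenericFoodEntry]
    participants: list[Participant]
    truth: GroundTruth
    transactions: pd.DataFrame
    ffq: pd.DataFrame

    @property
    def catalogue_df(self) -> pd.DataFrame:
        return catalogue_frame(self.products)

    @property
    def generics_df(self) -> pd.DataFrame:
        return generics_frame(self.generics)

    @property
    def participants_df(self) -> pd.DataFrame:
        return participants_frame(self.participants)

    @property
    def members_df(self) -> pd.DataFrame:
        return members_frame(self.participants)


def generate_dataset(config: GeneratorConfig) -> Dataset:
    """Run all three generator stages."""
    products, generics = generate_catalogue(config)
    participants, truth = generate_cohort(config)
    transactions, ffq = generate_observations(config, participants, (products, generics), truth)
    return Dataset(config, products, generics, participants, truth, transactions, ffq)


def waves_frame(config: GeneratorConfig) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "wave": w.label,
                "study_start": w.study_start.isoformat(),
                "comparison_start": w.comparison_start.isoformat(),
                "comparison_days": config.comparison_days,
            }
            for w in config.wave_scheme
        ]
    )


def write_dataset(dataset: Dataset, outdir) -> dict[str, Path]:
    """Write the dataset as the documented CSV files plus ground_truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    frames = {
        "catalogue.csv": dataset.catalogue_df,
        "generic_table.csv": dataset.generics_df,
        "participants.csv": dataset.participants_df,
        "household_members.csv": dataset.members_df,
        "transactions.csv": dataset.transactions,
        "ffq.csv": dataset.ffq,
        "waves.csv": waves_frame(dataset.config),
    }
    for name, df in frames.items():
        path = outdir / name
        df.to_csv(path, index=False)
        paths[name] = path

    truth = dataset.truth
    payload = {
        "ratio_intercept": truth.ratio_intercept,
        "ratio_slope": truth.ratio_slope,
        "ratio_noise_sd": truth.ratio_noise_sd,
        "per_participant": {
            pid: {
                "mean_log": t.mean_log,
                "log_diff": t.log_diff,
                "share": t.share,
                "true_retailer_share": t.true_retailer_share,
                "true_intake": dict(zip(NUTRIENT_FIELDS, t.true_intake.as_tuple())),
                "ffq_intake": dict(zip(NUTRIENT_FIELDS, t.ffq_intake.as_tuple())),
                "purchase_individual": dict(
                    zip(NUTRIENT_FIELDS, t.purchase_individual.as_tuple())
                ),
            }
            for pid, t in truth.per_participant.items()
        },
    }
    path = outdir / "ground_truth.json"
    path.write_text(json.dumps(payload, indent=1))
    paths["ground_truth.json"] = path
    return paths
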