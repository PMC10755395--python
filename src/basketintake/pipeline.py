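"""End-to-end orchestration: generate/load -> estimate -> allocate ->
compose -> filter -> agreement tables.

A :class:`RunConfig` either embeds a :class:`~basketintake.simulate.
GeneratorConfig` (self-contained synthetic run) or points at a
directory of input CSVs in the documented schemas. :func:`run` executes
every stage in order and returns a :class:`RunReport` whose tables
mirror the study-style outputs: an exclusion ledger, descriptive
statistics for absolute and relative measures, pooled and subgroup
agreement coefficient tables, and the sensitivity-analysis variants.
Identical config + seed reproduces byte-identical CSV output.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from . import __version__ as _pkg_version
from .agreement import agreement_by_measure, classic_ba, default_measures, pearson_r
from .allocation import HouseholdMember, allocation_share, load_recommendation_table
from .errors import ConfigurationError, DataError
from .estimation import ComparisonPeriod, daily_household_frame, effective_per100_frame, resolve_frame
from .filters import (
    ExclusionLedger,
    apply_exclusions,
    assign_subgroups_frame,
    sensitivity_filter,
)
from .nutrients import NUTRIENT_FIELDS, RelativeProfile, relative_profile_frame
from .simulate import Dataset, GeneratorConfig, generate_dataset

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """One reproducible analysis run.

    Exactly one of ``generator`` (self-contained synthetic run) or
    ``input_dir`` (pre-existing CSVs) must be set.
    """

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    generator: GeneratorConfig | None = None
    input_dir: str | None = None
    recommendation_table: str | None = None
    sensitivity_enabled: bool = True
    sensitivity_threshold_kcal: float = 500.0
    sensitivity_level: str = "household"
    group_by: tuple[str, ...] = ("household_size_group", "loyalty_group")
    a_kcal: float = 2000.0
    energy_outlier_kcal: float = 8000.0

    @model_validator(mode="after")
    def _one_source(self) -> "RunConfig":
        if (self.generator is None) == (self.input_dir is None):
            raise ValueError("exactly one of generator / input_dir must be set")
        if self.a_kcal <= 0:
            raise ValueError("a_kcal: prediction magnitudes must be > 0")
        return self


@dataclass
class InputBundle:
    """The raw tables one run consumes."""

    catalogue: pd.DataFrame
    generics: pd.DataFrame
    participants: pd.DataFrame
    members: pd.DataFrame
    transactions: pd.DataFrame
    ffq: pd.DataFrame
    waves: pd.DataFrame


def bundle_from_dataset(ds: Dataset) -> InputBundle:
    from .simulate import waves_frame

    return InputBundle(
        catalogue=ds.catalogue_df,
        generics=ds.generics_df,
        participants=ds.participants_df,
        members=ds.members_df,
        transactions=ds.transactions,
        ffq=ds.ffq,
        waves=waves_frame(ds.config),
    )


def bundle_from_dir(path) -> InputBundle:
    path = Path(path)
    def read(name):
        f = path / name
        if not f.exists():
            raise ConfigurationError(f"input_dir: missing required file {name}")
        return pd.read_csv(f)

    return InputBundle(
        catalogue=read("catalogue.csv"),
        generics=read("generic_table.csv"),
        participants=read("participants.csv"),
        members=read("household_members.csv"),
        transactions=read("transactions.csv"),
        ffq=read("ffq.csv"),
        waves=read("waves.csv"),
    )


@dataclass
class RunReport:
    """All outputs of one run, writable as CSV files."""

    config: RunConfig
    ledger: ExclusionLedger
    match_rates: tuple[float, float]
    analysis: pd.DataFrame
    descriptives_absolute: pd.DataFrame
    descriptives_relative: pd.DataFrame
    classic_table: pd.DataFrame
    agreement_pooled: pd.DataFrame
    agreement_subgroups: dict[str, pd.DataFrame]
    sensitivity_n_excluded: int | None = None
    sensitivity_pooled: pd.DataFrame | None = None
    sensitivity_subgroups: dict[str, pd.DataFrame] = field(default_factory=dict)
    energy_pearson_r: float | None = None

    def provenance(self) -> dict:
        cfg = json.loads(self.config.model_dump_json())
        digest = hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()
        return {
            "config": cfg,
            "config_sha256": digest,
            "seed": self.config.generator.seed if self.config.generator else None,
            "package_version": _pkg_version,
            "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        }

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        tables = {
            "exclusion_ledger.csv": self.ledger.to_frame(),
            "analysis_set.csv": self.analysis,
            "descriptives_absolute.csv": self.descriptives_absolute,
            "descriptives_relative.csv": self.descriptives_relative,
            "classic_bland_altman.csv": self.classic_table,
            "agreement_pooled.csv": self.agreement_pooled,
        }
        for key, frame in self.agreement_subgroups.items():
            tables[f"agreement_by_{key}.csv"] = frame
        if self.sensitivity_pooled is not None:
            tables["agreement_pooled_sensitivity.csv"] = self.sensitivity_pooled
            for key, frame in self.sensitivity_subgroups.items():
                tables[f"agreement_by_{key}_sensitivity.csv"] = frame
        for name, frame in tables.items():
            p = outdir / name
            frame.to_csv(p, index=False)
            paths[name] = p
        prov = dict(self.provenance())
        prov["match_rate_pre_imputation"] = self.match_rates[0]
        prov["match_rate_post_imputation"] = self.match_rates[1]
        prov["sensitivity_n_excluded"] = self.sensitivity_n_excluded
        prov["energy_pearson_r"] = self.energy_pearson_r
        p = outdir / "provenance.json"
        p.write_text(json.dumps(prov, indent=1, default=str))
        paths["provenance.json"] = p
        return paths


def _periods_by_customer(
    participants: pd.DataFrame, waves: pd.DataFrame
) -> dict[str, ComparisonPeriod]:
    wmap = {}
    for _, w in waves.iterrows():
        start = dt.date.fromisoformat(str(w["comparison_start"]))
        wmap[w["wave"]] = ComparisonPeriod.from_days(start, int(w["comparison_days"]))
    missing = set(participants["wave"]) - set(wmap)
    if missing:
        raise DataError(f"waves.csv missing wave definitions: {sorted(missing)}")
    return {
        row["customer_id"]: wmap[row["wave"]] for _, row in participants.iterrows()
    }


def _shares(participants: pd.DataFrame, members: pd.DataFrame, table) -> pd.Series:
    grouped = (
        members.groupby("participant_id")[["age_years", "gender"]].apply(
            lambda g: list(zip(g["age_years"], g["gender"]))
        )
        if len(members)
        else pd.Series(dtype=object)
    )
    out = {}
    for _, row in participants.iterrows():
        others = [HouseholdMember(int(a), "unknown") for a, _ in grouped.get(row["participant_id"], [])]
        out[row["participant_id"]] = allocation_share(
            HouseholdMember(int(row["age_years"]), row["gender"]), others, table
        )
    return pd.Series(out, name="share")


def _match_rates(transactions: pd.DataFrame, catalogue: pd.DataFrame, generics: pd.DataFrame) -> tuple[float, float]:
    eff = effective_per100_frame(catalogue, generics)
    purchased = pd.Series(sorted(set(transactions["product_id"])), name="product_id")
    prov = purchased.map(eff.set_index("product_id")["provenance"])
    if prov.isna().any():
        raise DataError("transactions reference products absent from the catalogue")
    pre = float((prov == "retailer").mean())
    return pre, 1.0


def build_analysis_table(bundle: InputBundle, config: RunConfig) -> tuple[pd.DataFrame, ExclusionLedger, tuple[float, float]]:
    """Per-participant wide table of all measures, after exclusions.

    Columns: household_/individual_/intake_ prefixed absolute analytes,
    purchase_/intake_ prefixed relative measures, the allocation share,
    subgroup labels and wave.
    """
    table = load_recommendation_table(config.recommendation_table)
    resolved = resolve_frame(bundle.transactions, bundle.catalogue, bundle.generics)
    match_rates = _match_rates(bundle.transactions, bundle.catalogue, bundle.generics)
    logger.info(
        "match rate: %.1f%% of purchased products pre-imputation, %.1f%% after",
        100 * match_rates[0],
        100 * match_rates[1],
    )
    periods = _periods_by_customer(bundle.participants, bundle.waves)
    household = daily_household_frame(resolved, periods)

    wide = bundle.participants.merge(
        household.rename(columns={f: f"household_{f}" for f in NUTRIENT_FIELDS}),
        on="customer_id",
        how="left",
        validate="one_to_one",
    )
    shares = _shares(bundle.participants, bundle.members, table)
    wide["share"] = wide["participant_id"].map(shares)
    for f in NUTRIENT_FIELDS:
        wide[f"individual_{f}"] = wide[f"household_{f}"] * wide["share"]
    wide = wide.merge(
        bundle.ffq.rename(columns={f: f"intake_{f}" for f in NUTRIENT_FIELDS}),
        on="participant_id",
        how="left",
        validate="one_to_one",
    )

    estimates = wide[["participant_id", "n_lines"]].copy()
    estimates["energy_kcal"] = wide["household_energy_kcal"]
    ffq_for_excl = bundle.ffq[["participant_id", "energy_kcal"]]
    retained, ledger = apply_exclusions(
        wide, ffq_for_excl, estimates, energy_outlier_kcal=config.energy_outlier_kcal
    )

    rel_purchase = relative_profile_frame(retained, prefix="individual_", out_prefix="purchase_")
    rel_intake = relative_profile_frame(retained, prefix="intake_", out_prefix="intake_")
    analysis = pd.concat([retained, rel_purchase, rel_intake], axis=1)
    analysis = assign_subgroups_frame(analysis)
    return analysis, ledger, match_rates


def descriptives(analysis: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean and sd per measure: absolute at three levels, relative at two.

    With a single participant the sd is reported as missing (NaN), not
    zero.
    """
    if analysis.empty:
        raise DataError("descriptives need a non-empty analysis set")
    abs_rows = []
    for f in NUTRIENT_FIELDS:
        for level in ("household", "individual", "intake"):
            vals = analysis[f"{level}_{f}"]
            abs_rows.append(
                {
                    "measure": f,
                    "level": level,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                }
            )
    rel_rows = []
    for r in RelativeProfile.MEASURES:
        row = {"measure": r}
        for side in ("purchase", "intake"):
            vals = analysis[f"{side}_{r}"]
            row[f"{side}_mean"] = float(vals.mean())
            row[f"{side}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
        rel_rows.append(row)
    return pd.DataFrame(abs_rows), pd.DataFrame(rel_rows)


def _classic_table(analysis: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for level in ("household", "individual"):
        for f in NUTRIENT_FIELDS:
            res = classic_ba(analysis[f"{level}_{f}"], analysis[f"intake_{f}"])
            rows.append(
                {
                    "measure": f"{level}:{f}",
                    "n": res.n,
                    "mean_diff": res.mean_diff,
                    "sd_diff": res.sd_diff,
                    "loa_lo": res.loa_lo,
                    "loa_hi": res.loa_hi,
                }
            )
    return pd.DataFrame(rows)


def _agreement_tables(analysis: pd.DataFrame, config: RunConfig):
    pooled = agreement_by_measure(analysis, A_kcal=config.a_kcal)
    subgroups = {}
    energy_measures = [m for m in default_measures() if m[0] == "individual:energy_kcal"]
    for key in config.group_by:
        subgroups[key] = agreement_by_measure(
            analysis, measures=energy_measures, group_by=key, A_kcal=config.a_kcal
        )
    return pooled, subgroups


def run(config: RunConfig) -> RunReport:
    """Execute a full configured run and return its report."""
    if config.generator is not None:
        bundle = bundle_from_dataset(generate_dataset(config.generator))
    else:
        bundle = bundle_from_dir(config.input_dir)

    analysis, ledger, match_rates = build_analysis_table(bundle, config)
    if analysis.empty:
        raise DataError("analysis set is empty after exclusions")
    desc_abs, desc_rel = descriptives(analysis)
    classic = _classic_table(analysis)
    pooled, subgroups = _agreement_tables(analysis, config)
    r = pearson_r(analysis["household_energy_kcal"], analysis["intake_energy_kcal"])

    report = RunReport(
        config=config,
        ledger=ledger,
        match_rates=match_rates,
        analysis=analysis,
        descriptives_absolute=desc_abs,
        descriptives_relative=desc_rel,
        classic_table=classic,
        agreement_pooled=pooled,
        agreement_subgroups=subgroups,
        energy_pearson_r=r,
    )

    if config.sensitivity_enabled:
        estimates = analysis[["participant_id"]].copy()
        estimates["n_lines"] = analysis["n_lines"]
        estimates["energy_kcal"] = analysis["household_energy_kcal"]
        shares = analysis.set_index("participant_id")["share"]
        subset, n_excl = sensitivity_filter(
            analysis,
            estimates,
            threshold_kcal=config.sensitivity_threshold_kcal,
            level=config.sensitivity_level,
            shares=shares,
        )
        report.sensitivity_n_excluded = n_excl
        logger.info("sensitivity filter excluded %d participants", n_excl)
        if len(subset) >= 3:
            report.sensitivity_pooled, report.sensitivity_subgroups = _agreement_tables(
                subset, config
            )
    return report
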