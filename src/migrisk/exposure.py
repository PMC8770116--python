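"""Mouthing exposure doses and hazard-quotient risk screening.

A migration rate becomes a daily dose through the mouthing scenario:

    E_mouthing = Δt_mouthing × (A_contact / 10 cm²) × R_mgr / BW

with Δt_mouthing (min/d) = mouthing duration (min/h) × active hours per
day, R_mgr in µg/10cm²/min and BW the child's body weight (kg), giving
µg/kg_BW/d. Dividing by the chemical's oral reference dose yields the
hazard quotient HQ = E/RfD; HQ > 1 flags a combination of concern.

Four built-in scenarios cross two age groups (3 to <6 months, 2 to <3
years) with average and 99th-percentile mouthing durations, separately
for pacifiers (mouthed long-term) and dolls (mouthed occasionally).
Durations are day-averaged min/h, so the default active_hours_per_day is
24; both are explicit, overridable scenario parameters.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError

__all__ = [
    "AgeGroup",
    "ExposureEstimate",
    "MouthingScenario",
    "Percentile",
    "RiskRecord",
    "builtin_scenarios",
    "daily_exposure",
    "hazard_quotient",
    "load_rfd_table",
    "load_scenarios",
    "risk_summary",
    "screen_inventory",
]

#: HQ level above which a chemical-material combination is of concern.
HQ_CONCERN_THRESHOLD = 1.0


class AgeGroup(str, enum.Enum):
    M3_TO_6 = "3_to_6_months"
    Y2_TO_3 = "2_to_3_years"


class Percentile(str, enum.Enum):
    AVERAGE = "average"
    P99 = "p99"


@dataclass(frozen=True)
class MouthingScenario:
    age_group: AgeGroup
    percentile: Percentile
    bw: float  # body weight, kg
    duration_pacifier: float  # min/h, day-averaged
    duration_doll: float  # min/h, day-averaged
    active_hours_per_day: float = 24.0

    def __post_init__(self) -> None:
        if not (self.bw > 0):
            raise DomainError(f"bw must be > 0, got {self.bw}")
        if self.duration_pacifier < 0 or self.duration_doll < 0:
            raise DomainError("mouthing durations must be >= 0")
        if not (0 < self.active_hours_per_day <= 24):
            raise DomainError("active_hours_per_day must be in (0, 24]")

    @property
    def label(self) -> str:
        return f"{self.age_group.value}:{self.percentile.value}"

    def duration_for(self, archetype: str) -> float:
        if archetype == "pacifier":
            return self.duration_pacifier
        if archetype == "doll":
            return self.duration_doll
        raise DomainError(f"unknown product archetype {archetype!r}")


def builtin_scenarios() -> tuple[MouthingScenario, ...]:
    """The four standard mouthing scenarios (age group × duration percentile).

    Body weights and day-averaged mouthing durations (min/h): 3 to <6
    months, 7.4 kg — pacifier 3.4 / doll 0.5 average, 37.3 / 2.5 at the
    99th percentile; 2 to <3 years, 13.8 kg — 1.8 / 0.4 average,
    46.3 / 2.9 at the 99th percentile.
    """
    return (
        MouthingScenario(AgeGroup.M3_TO_6, Percentile.AVERAGE, 7.4, 3.4, 0.5),
        MouthingScenario(AgeGroup.M3_TO_6, Percentile.P99, 7.4, 37.3, 2.5),
        MouthingScenario(AgeGroup.Y2_TO_3, Percentile.AVERAGE, 13.8, 1.8, 0.4),
        MouthingScenario(AgeGroup.Y2_TO_3, Percentile.P99, 13.8, 46.3, 2.9),
    )


def load_scenarios(path: str | Path) -> tuple[MouthingScenario, ...]:
    """Load scenarios from a YAML document (list under key ``scenarios``)."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    out = []
    for rec in doc["scenarios"]:
        out.append(MouthingScenario(
            age_group=AgeGroup(rec["age_group"]),
            percentile=Percentile(rec["percentile"]),
            bw=float(rec["bw_kg"]),
            duration_pacifier=float(rec["duration_pacifier_min_h"]),
            duration_doll=float(rec["duration_doll_min_h"]),
            active_hours_per_day=float(rec.get("active_hours_per_day", 24.0)),
        ))
    return tuple(out)


class RateSource(str, enum.Enum):
    MECHANISTIC = "mechanistic"
    REGRESSION = "regression"
    EXPERIMENTAL = "experimental"


@dataclass(frozen=True)
class ExposureEstimate:
    e_mouthing: float  # ug/kg_BW/d
    scenario: MouthingScenario
    product_archetype: str
    rate_source: RateSource = RateSource.EXPERIMENTAL


@dataclass(frozen=True)
class RiskRecord:
    exposure: ExposureEstimate
    rfd: float  # ug/kg_BW/d
    rfd_source: str  # "experimental" | "qsar_predicted"
    hq: float


def daily_exposure(
    rate: float,
    scenario: MouthingScenario,
    archetype: str,
    a_contact: float = 10.0,
    rate_source: RateSource = RateSource.EXPERIMENTAL,
) -> ExposureEstimate:
    """Daily mouthing dose (µg/kg_BW/d) from a migration rate.

    ``rate`` is per 10 cm² per minute; ``a_contact`` rescales to the
    actual mouthed area. The archetype picks which scenario duration
    applies.
    """
    if rate < 0:
        raise DomainError(f"rate must be >= 0, got {rate}")
    if not (a_contact > 0):
        raise DomainError(f"a_contact must be > 0, got {a_contact}")
    dt_min_per_day = scenario.duration_for(archetype) * scenario.active_hours_per_day
    e = dt_min_per_day * (a_contact / 10.0) * rate / scenario.bw
    return ExposureEstimate(
        e_mouthing=e, scenario=scenario, product_archetype=archetype,
        rate_source=rate_source,
    )


def hazard_quotient(
    e: ExposureEstimate | float, rfd: float, rfd_source: str = "experimental"
) -> RiskRecord:
    """HQ = E_mouthing / RfD. ``rfd_source`` records provenance only."""
    if not (rfd > 0) or not math.isfinite(rfd):
        raise DomainError(f"rfd must be finite and > 0, got {rfd}")
    est = e if isinstance(e, ExposureEstimate) else ExposureEstimate(
        e_mouthing=float(e),
        scenario=builtin_scenarios()[0],
        product_archetype="doll",
    )
    if est.e_mouthing < 0:
        raise DomainError("exposure must be >= 0")
    return RiskRecord(exposure=est, rfd=rfd, rfd_source=rfd_source,
                      hq=est.e_mouthing / rfd)


def load_rfd_table(path: str | Path) -> pd.DataFrame:
    """Read an RfD table CSV: chemical_key, rfd_ug_per_kg_d, rfd_source.

    ``chemical_key`` is the CAS number when available, else the
    lower-cased chemical name.
    """
    df = pd.read_csv(path, dtype={"chemical_key": str})
    needed = {"chemical_key", "rfd_ug_per_kg_d"}
    missing = needed - set(df.columns)
    if missing:
        raise DomainError(f"RfD table missing columns {sorted(missing)}")
    if "rfd_source" not in df.columns:
        df["rfd_source"] = "experimental"
    return df


def _chemical_key(row: Mapping) -> str:
    cas = str(row.get("chemical_cas", "") or "").strip()
    return cas if cas else str(row.get("chemical_name", "")).strip().lower()


def screen_inventory(
    df: pd.DataFrame,
    rfd_table: pd.DataFrame,
    scenarios: Sequence[MouthingScenario] | None = None,
    rate_column: str = "rate_ug_per_10cm2_min",
    rate_source: RateSource = RateSource.EXPERIMENTAL,
    a_contact_column: str = "sample_area_cm2",
    hq_threshold: float = HQ_CONCERN_THRESHOLD,
) -> pd.DataFrame:
    """One risk record per (input row × scenario).

    Rows without a matching RfD are kept with NaN HQ and flagged, never
    dropped. Each record carries a ``concern`` classification: ``concern``
    if HQ exceeds the threshold in the average scenario of its age group,
    ``upper_bound_only`` if it exceeds only at the 99th percentile, else
    ``none``. Output is sorted by descending HQ.
    """
    scenarios = tuple(scenarios) if scenarios is not None else builtin_scenarios()
    rfd_map = {
        str(r["chemical_key"]): (float(r["rfd_ug_per_kg_d"]), str(r["rfd_source"]))
        for _, r in rfd_table.iterrows()
    }
    records = []
    for row_id, row in df.iterrows():
        key = _chemical_key(row)
        rfd, rfd_source = rfd_map.get(key, (np.nan, ""))
        rate = float(row[rate_column])
        archetype = str(row["product_archetype"])
        a_contact = float(row.get(a_contact_column, 10.0) or 10.0)
        for sc in scenarios:
            est = daily_exposure(rate, sc, archetype, a_contact=a_contact,
                                 rate_source=rate_source)
            flags = [] if key in rfd_map else ["missing_rfd"]
            records.append({
                "row_id": row_id,
                "chemical_key": key,
                "chemical_name": row.get("chemical_name", ""),
                "material": row.get("material", ""),
                "product_archetype": archetype,
                "age_group": sc.age_group.value,
                "percentile": sc.percentile.value,
                "scenario": sc.label,
                "rate_ug_per_10cm2_min": rate,
                "e_mouthing_ug_per_kg_d": est.e_mouthing,
                "rfd_ug_per_kg_d": rfd,
                "rfd_source": rfd_source,
                "hq": est.e_mouthing / rfd if rfd > 0 else np.nan,
                "flags": ";".join(flags),
            })
    out = pd.DataFrame(records)
    if out.empty:
        return out

    # classify concern per (row, age group): average-scenario exceedance
    # is "concern"; p99-only exceedance is "upper_bound_only"
    keys = ["row_id", "age_group"]
    avg_hit = out[out["percentile"] == Percentile.AVERAGE.value].groupby(keys)["hq"].apply(
        lambda s: bool((s > hq_threshold).any())
    )
    p99_hit = out[out["percentile"] == Percentile.P99.value].groupby(keys)["hq"].apply(
        lambda s: bool((s > hq_threshold).any())
    )
    idx = pd.MultiIndex.from_frame(out[keys])
    a = avg_hit.reindex(idx).fillna(False).to_numpy(dtype=bool)
    p = p99_hit.reindex(idx).fillna(False).to_numpy(dtype=bool)
    out["concern"] = np.where(a, "concern", np.where(p, "upper_bound_only", "none"))
    return out.sort_values("hq", ascending=False, na_position="last").reset_index(drop=True)


def risk_summary(risk: pd.DataFrame, hq_threshold: float = HQ_CONCERN_THRESHOLD,
                 top_k: int = 10) -> dict:
    """Machine-readable screening summary: exceedance counts per scenario
    and the top-k records by HQ."""
    summary: dict = {"hq_threshold": hq_threshold, "n_records": int(len(risk)),
                     "n_missing_rfd": int((risk["flags"] == "missing_rfd").sum()),
                     "exceedances_per_scenario": {}}
    for label, group in risk.groupby("scenario"):
        summary["exceedances_per_scenario"][label] = int((group["hq"] > hq_threshold).sum())
    top = risk.dropna(subset=["hq"]).nlargest(top_k, "hq")
    summary["top_hq"] = [
        {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
         for k, v in rec.items()
         if k in ("chemical_key", "material", "scenario", "hq",
                  "e_mouthing_ug_per_kg_d", "rfd_ug_per_kg_d")}
        for rec in top.to_dict("records")
    ]
    return summary
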