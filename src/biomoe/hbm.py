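"""Ingestion and validation of aggregated biomonitoring percentile records.

Aggregated human-biomonitoring (HBM) studies report population percentiles
of a urinary biomarker rather than individual samples: typically the median
(P50) for the average population, the 95th percentile (P95) for the highly
exposed group, and the upper bound of the 95% confidence interval of P95 for
the most exposed individuals.  Studies that only publish other statistics
may declare fallbacks (geometric mean for the P50 slot, P75 for the P95
slot, observed maximum for the upper-CI slot); the tier labels in reports
disclose the substitution.

Missing values are written ``n.r.`` (not reported, e.g. because most samples
fell below the detection limit) or left empty; both parse to missing.
Records with missing percentiles are retained but flagged, so they are
excluded from margin-of-exposure computations for the affected tiers without
being silently dropped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "Tier",
    "HBMRecord",
    "CreatinineModel",
    "correct_creatinine",
    "validate_records",
    "read_hbm_csv",
    "ValidationLog",
]

MISSING_TOKENS = {"", "n.r.", "nr", "n.r", "na", "nan"}


class Tier(str, Enum):
    """Exposure tiers of an aggregated record, from average to extreme."""

    p50 = "P50"
    p95 = "P95"
    upper_ci = "upperCI"
    max = "max"


class HBMRecord(BaseModel):
    """One aggregated percentile record for one study population."""

    study_id: str
    country: str = ""
    population: str = "adults"
    years: str = ""
    n: Optional[int] = Field(default=None, ge=1)
    p50: Optional[float] = Field(default=None, gt=0)
    p95: Optional[float] = Field(default=None, gt=0)
    upper_ci_p95: Optional[float] = Field(default=None, gt=0)
    max_value: Optional[float] = Field(default=None, gt=0)
    adjusted: bool = False
    #: which statistic fills each tier when the canonical one is unavailable
    tier_sources: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _ordered(self) -> "HBMRecord":
        present = [v for v in (self.p50, self.p95, self.upper_ci_p95) if v is not None]
        if present != sorted(present):
            raise ValueError(
                f"{self.study_id}: percentile ordering violated "
                f"(require p50 <= p95 <= upper CI)"
            )
        return self

    def tier_value(self, tier: Tier) -> Optional[float]:
        return {
            Tier.p50: self.p50,
            Tier.p95: self.p95,
            Tier.upper_ci: self.upper_ci_p95,
            Tier.max: self.max_value,
        }[tier]

    def usable_for(self, tier: Tier) -> bool:
        return self.tier_value(tier) is not None


@dataclass
class ValidationLog:
    """Problems found during ingestion, keyed by study id."""

    issues: list[tuple[str, str]] = field(default_factory=list)

    def add(self, study_id: str, message: str) -> None:
        self.issues.append((study_id, message))

    def __len__(self) -> int:
        return len(self.issues)


class CreatinineModel(BaseModel):
    """Linear correlation converting ug/g-creatinine to volume-based ug/L.

    The coefficients come from a study-specific regression of adjusted
    against unadjusted concentrations; they are deliberately not defaulted
    to anything but the identity, which triggers a warning.
    """

    intercept: float = 0.0
    slope: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "CreatinineModel":
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        return self

    @property
    def is_identity(self) -> bool:
        return self.intercept == 0.0 and self.slope == 1.0


def correct_creatinine(
    value: float, model: CreatinineModel | None = None
) -> float:
    """Convert a creatinine-adjusted concentration to a volume basis.

    Returns ``intercept + slope * value`` (ug/L).  With no model configured
    the identity is applied and a warning emitted, because no universal
    adjusted-to-unadjusted correlation exists.
    """
    if value <= 0:
        raise ValueError("concentration must be strictly positive")
    if model is None:
        model = CreatinineModel()
    if model.is_identity:
        warnings.warn(
            "no creatinine correlation configured; applying identity "
            "(adjusted values passed through unchanged)",
            stacklevel=2,
        )
    out = model.intercept + model.slope * value
    if out <= 0:
        raise ValueError(
            f"creatinine correction produced non-positive value {out!r}"
        )
    return out


def validate_records(
    records: Iterable[HBMRecord | dict],
) -> tuple[list[HBMRecord], ValidationLog]:
    """Validate raw records, routing every problem to an issue log.

    Clean records pass through bit-identical.  Records with missing
    percentiles are retained and flagged in the log (they remain usable for
    the tiers they do report); ordering violations and other structural
    failures are rejected to the log.
    """
    log = ValidationLog()
    clean: list[HBMRecord] = []
    for raw in records:
        try:
            rec = raw if isinstance(raw, HBMRecord) else HBMRecord(**raw)
        except Exception as err:
            study = (
                raw.study_id if isinstance(raw, HBMRecord)
                else str(raw.get("study_id", "<unknown>"))
            )
            log.add(study, f"rejected: {err}")
            continue
        missing = [t.value for t in (Tier.p50, Tier.p95, Tier.upper_ci)
                   if rec.tier_value(t) is None]
        if missing:
            log.add(rec.study_id, f"missing tiers: {', '.join(missing)}")
        if rec.adjusted:
            log.add(rec.study_id, "creatinine-adjusted units; correction required")
        clean.append(rec)
    return clean, log


def _parse_cell(cell: object) -> Optional[float]:
    if cell is None:
        return None
    if isinstance(cell, float) and math.isnan(cell):
        return None
    text = str(cell).strip().lower()
    if text in MISSING_TOKENS:
        return None
    return float(cell)


def read_hbm_csv(path: str | Path) -> list[HBMRecord | dict]:
    """Read an aggregated-percentile CSV into raw record dicts.

    Expected columns: study_id, country, population, years, n, p50, p95,
    upper_ci_p95, max, adjusted.  ``n.r.`` and empty cells parse as missing.
    The output feeds :func:`validate_records`; rows that fail model
    validation there are reported, not raised.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    records: list[dict] = []
    for _, row in df.iterrows():
        n_raw = _parse_cell(row.get("n"))
        records.append(
            dict(
                study_id=str(row["study_id"]).strip(),
                country=str(row.get("country", "")).strip(),
                population=str(row.get("population", "")).strip(),
                years=str(row.get("years", "")).strip(),
                n=int(n_raw) if n_raw is not None else None,
                p50=_parse_cell(row.get("p50")),
                p95=_parse_cell(row.get("p95")),
                upper_ci_p95=_parse_cell(row.get("upper_ci_p95")),
                max_value=_parse_cell(row.get("max")),
                adjusted=str(row.get("adjusted", "false")).strip().lower()
                in {"true", "1", "yes"},
            )
        )
    return records
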