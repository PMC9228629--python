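"""Forward model: dietary %ADI exposure records -> predicted urinary TCPy.

EU annual monitoring reports express per-diet chronic dietary exposure as
the highest calculated percentage of the acceptable daily intake (ADI).
Given the ADI in force in a report year, the chain is

    dose (mg/kg bw/day)   = %ADI / 100 * ADI(pesticide, year)
    urinary conc (ug/L)   = sum_pesticides(dose * molar_ratio) * Fue / V_urine

with V_urine the food-model urinary output of 0.024 L/kg bw/day.  Both
chlorpyrifos and chlorpyrifos-methyl contribute TCPy, summed on a molar
basis.  Per-year distributions over diets are summarised with box-whisker
order statistics.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .dosimetry import ToxicokineticParams, dose_to_urine_conc

__all__ = [
    "DietExposureRecord",
    "YearlySummary",
    "percent_adi_to_dose",
    "predict_diet_tcpy",
    "predict_all_diets",
    "summarize_year",
    "read_diet_csv",
]

logger = logging.getLogger(__name__)

AdiTable = Mapping[tuple[str, int], float]


class DietExposureRecord(BaseModel):
    """Highest calculated chronic exposure for one diet, year and pesticide."""

    diet_label: str
    year: int
    population: str = "general"
    pesticide: str
    percent_adi: float = Field(ge=0)


class YearlySummary(BaseModel):
    """Box-whisker order statistics of predicted concentrations for a year."""

    year: int
    population: str
    n_diets: int = Field(ge=1)
    min: float
    q1: float
    median: float
    mean: float
    q3: float
    max: float

    @model_validator(mode="after")
    def _ordered(self) -> "YearlySummary":
        if not (self.min <= self.q1 <= self.median <= self.q3 <= self.max):
            raise ValueError("order statistics must be non-decreasing")
        if not (self.min <= self.mean <= self.max):
            raise ValueError("mean must lie within [min, max]")
        return self


def _lookup_adi(adi: AdiTable, pesticide: str, year: int) -> float:
    try:
        return adi[(pesticide, year)]
    except KeyError:
        raise ValueError(
            f"no ADI configured for pesticide {pesticide!r} in year {year}"
        ) from None


def percent_adi_to_dose(rec: DietExposureRecord, adi: AdiTable) -> float:
    """External dose (mg/kg bw/day) behind a reported %-of-ADI figure."""
    return rec.percent_adi / 100.0 * _lookup_adi(adi, rec.pesticide, rec.year)


def predict_diet_tcpy(
    records: Sequence[DietExposureRecord],
    adi: AdiTable,
    tk: ToxicokineticParams,
    molar_ratios: Mapping[str, float],
) -> float:
    """Predicted total urinary TCPy (ug/L) for one diet-year.

    All records must share diet label and year; each pesticide contributes
    on a molar basis.  A diet reported for only one of the two parents is
    treated as zero contribution from the other (logged at INFO level).
    """
    if not records:
        return 0.0
    labels = {(r.diet_label, r.year) for r in records}
    if len(labels) > 1:
        raise ValueError(f"records mix diet-years: {sorted(labels)}")
    missing = set(molar_ratios) - {r.pesticide for r in records}
    if missing:
        logger.info(
            "diet %r year %s: no record for %s; assuming zero contribution",
            records[0].diet_label, records[0].year, ", ".join(sorted(missing)),
        )
    doses = [(r.pesticide, percent_adi_to_dose(r, adi)) for r in records]
    return dose_to_urine_conc(
        doses, molar_ratios, tk.fue, tk.urine_output_food_model
    )


def predict_all_diets(
    records: Iterable[DietExposureRecord],
    adi: AdiTable,
    tk: ToxicokineticParams,
    molar_ratios: Mapping[str, float],
) -> pd.DataFrame:
    """Per-(diet, year, population) predicted concentrations as a DataFrame."""
    df = pd.DataFrame([r.model_dump() for r in records])
    if df.empty:
        return pd.DataFrame(
            columns=["diet_label", "year", "population", "tcpy_ugl"]
        )
    rows = []
    for (label, year, pop), grp in df.groupby(
        ["diet_label", "year", "population"], sort=True
    ):
        recs = [DietExposureRecord(**r) for r in grp.to_dict("records")]
        rows.append(
            dict(
                diet_label=label,
                year=year,
                population=pop,
                tcpy_ugl=predict_diet_tcpy(recs, adi, tk, molar_ratios),
            )
        )
    return pd.DataFrame(rows)


def summarize_year(
    predictions: Sequence[float], year: int, population: str = "general"
) -> YearlySummary:
    """Box-whisker summary of one year's per-diet predictions.

    Quartiles use the linear-interpolation convention between order
    statistics; the mean is arithmetic.
    """
    if len(predictions) == 0:
        raise ValueError(f"no predictions to summarize for year {year}")
    arr = np.asarray(predictions, dtype=float)
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    lo, hi = float(arr.min()), float(arr.max())
    # the arithmetic mean lies in [min, max] mathematically; summation
    # round-off can push it a ulp outside, so clamp before validation
    mean = min(max(float(arr.mean()), lo), hi)
    return YearlySummary(
        year=year,
        population=population,
        n_diets=len(arr),
        min=lo,
        q1=float(q1),
        median=float(med),
        mean=mean,
        q3=float(q3),
        max=hi,
    )


def read_diet_csv(path) -> list[DietExposureRecord]:
    """Read diet exposure records from CSV.

    Columns: diet_label, year, population, pesticide, percent_adi.
    """
    df = pd.read_csv(path)
    return [
        DietExposureRecord(
            diet_label=str(row.diet_label),
            year=int(row.year),
            population=str(getattr(row, "population", "general")),
            pesticide=str(row.pesticide),
            percent_adi=float(row.percent_adi),
        )
        for row in df.itertuples(index=False)
    ]
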