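"""Synthetic inputs with the statistical structure the analysis assumes.

Urinary biomarker concentrations in a population are modelled as lognormal:
multiplicative variation around a median m with log-scale spread sigma, so
that quantile ratios are spread-only, e.g. P95/P50 = exp(1.645 * sigma).
Reported P95/P50 ratios of roughly 4 (sigma ~ 0.84) to 10 (sigma ~ 1.40)
are typical of the studies this emulates.  Individual draws are aggregated
to the percentile records the ingestion stage consumes, with a percentile
bootstrap supplying the upper confidence bound of P95.  A companion
generator emits %-of-ADI diet tables with a configurable pre/post
regulatory era shift.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .food import DietExposureRecord
from .hbm import HBMRecord

__all__ = [
    "PopulationModel",
    "simulate_population",
    "bootstrap_p95_ci",
    "aggregate_to_record",
    "simulate_diet_table",
]

#: standard normal 95th-percentile z-score used in quantile-ratio identities
Z95 = 1.6448536269514722


class PopulationModel(BaseModel):
    """Lognormal individual-level model for one study population."""

    median: float = Field(gt=0)
    sigma_log: float = Field(ge=0)
    n_individuals: int = Field(ge=1)
    seed: int
    lod: Optional[float] = Field(default=None, gt=0)

    @classmethod
    def from_p95_ratio(
        cls, median: float, p95_over_p50: float, n_individuals: int, seed: int,
        lod: float | None = None,
    ) -> "PopulationModel":
        """Parameterise the spread from a target P95/P50 ratio (>= 1)."""
        if p95_over_p50 < 1:
            raise ValueError("P95/P50 ratio must be >= 1")
        return cls(
            median=median,
            sigma_log=float(np.log(p95_over_p50)) / Z95,
            n_individuals=n_individuals,
            seed=seed,
            lod=lod,
        )


def simulate_population(model: PopulationModel) -> tuple[np.ndarray, np.ndarray]:
    """Draw individual urinary concentrations (ug/L).

    Returns ``(values, censored)`` where ``censored`` flags values below the
    detection limit (values are returned uncensored; downstream stages
    decide how to treat them).  Seeded and reproducible.
    """
    rng = np.random.default_rng(model.seed)
    values = model.median * np.exp(
        model.sigma_log * rng.standard_normal(model.n_individuals)
    )
    censored = (
        values < model.lod if model.lod is not None
        else np.zeros(model.n_individuals, dtype=bool)
    )
    return values, censored


def bootstrap_p95_ci(
    values: np.ndarray | Sequence[float],
    n_boot: int = 500,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Two-sided percentile-bootstrap confidence interval for P95.

    Resamples with replacement, takes the 95th percentile of each resample
    (linear-interpolation quantiles) and returns the (alpha/2, 1 - alpha/2)
    percentiles of the bootstrap distribution.
    """
    arr = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(n_boot, arr.size))
    boot_p95 = np.quantile(arr[idx], 0.95, axis=1, method="linear")
    alpha = 1.0 - level
    lo, hi = np.quantile(boot_p95, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def aggregate_to_record(
    values: np.ndarray | Sequence[float],
    study_id: str,
    *,
    country: str = "",
    population: str = "adults",
    years: str = "",
    n_boot: int = 500,
    seed: int = 0,
    censored: np.ndarray | None = None,
    censored_cutoff: float = 0.6,
) -> HBMRecord:
    """Aggregate individual values to the percentile record shape.

    P50/P95 use linear-interpolation quantiles; the upper CI of P95 is the
    97.5th percentile of the bootstrap distribution of P95.  When the
    censored fraction exceeds ``censored_cutoff`` the percentiles are
    reported missing, emulating studies withheld for detection-limit
    reasons.  Requires at least 20 values for the CI to be estimable.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 20:
        raise ValueError(f"need >= 20 values for CI estimation, got {arr.size}")
    base = dict(
        study_id=study_id, country=country, population=population,
        years=years, n=int(arr.size),
    )
    if censored is not None and censored.mean() > censored_cutoff:
        return HBMRecord(**base)  # all percentiles n.r.
    p50, p95 = np.quantile(arr, [0.5, 0.95], method="linear")
    _, upper = bootstrap_p95_ci(arr, n_boot=n_boot, seed=seed)
    # a bootstrap upper bound can land marginally below the sample P95 in
    # heavy-tailed small samples; clamp to preserve the tier ordering contract
    upper = max(upper, float(p95))
    return HBMRecord(
        **base,
        p50=float(p50),
        p95=float(p95),
        upper_ci_p95=upper,
        max_value=float(arr.max()),
    )


def simulate_diet_table(
    years: Sequence[int],
    n_diets: int,
    percent_adi_ranges: dict[str, dict[str, tuple[float, float]]],
    seed: int,
) -> list[DietExposureRecord]:
    """Synthetic %-of-ADI diet table across report years.

    ``percent_adi_ranges`` maps era label ("pre"/"post", split at 2016) to
    per-pesticide (low, high) uniform ranges for the reported %ADI.  Emits
    one record per diet x year x pesticide.
    """
    rng = np.random.default_rng(seed)
    records: list[DietExposureRecord] = []
    for year in years:
        era = "pre" if year < 2016 else "post"
        ranges = percent_adi_ranges[era]
        for d in range(n_diets):
            for pesticide, (lo, hi) in ranges.items():
                records.append(
                    DietExposureRecord(
                        diet_label=f"diet_{d:02d}",
                        year=year,
                        population="general",
                        pesticide=pesticide,
                        percent_adi=float(rng.uniform(lo, hi)),
                    )
                )
    return records
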