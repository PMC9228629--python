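"""Propagation of toxicokinetic parameter uncertainty into MoE intervals.

The dominant quantified uncertainty in the reverse-dosimetry chain is the
molar urinary excretion fraction Fue, stated as a central estimate of 0.7
within a 0.5-0.93 range.  Both the biomonitoring-equivalent PoD and the MoE
are linear in Fue, so interval endpoints follow from recomputing the chain
at the range bounds; a seeded triangular Monte Carlo over the same range
gives an empirical MoE distribution.  Exposure-side variability is already
encoded by the reported percentiles and is excluded by default.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .dosimetry import HBMPoD, PoDEntry, Population, ToxicokineticParams, hbm_pod
from .risk import moe

__all__ = ["UncertaintySpec", "moe_bounds", "moe_mc", "McSummary"]


class UncertaintySpec(BaseModel):
    """Triangular Fue distribution plus Monte-Carlo controls."""

    fue_low: float = 0.5
    fue_mode: float = 0.7
    fue_high: float = 0.93
    n_draws: int = Field(default=10_000, ge=1)
    seed: Optional[int] = None

    @model_validator(mode="after")
    def _ordered(self) -> "UncertaintySpec":
        if not (0 < self.fue_low <= self.fue_mode <= self.fue_high):
            raise ValueError("require 0 < low <= mode <= high")
        return self


def _moe_at_fue(
    pod: PoDEntry,
    exposure_ugl: float,
    tk: ToxicokineticParams,
    population: Population | str,
    fue: float,
) -> float:
    tk_at = tk.model_copy(update={"fue": fue, "fue_low": fue, "fue_high": fue})
    return moe(hbm_pod(pod, tk_at, population), exposure_ugl, use_reported=False)


def moe_bounds(
    pod: PoDEntry,
    exposure_ugl: float,
    tk: ToxicokineticParams,
    population: Population | str = Population.adults,
) -> tuple[float, float]:
    """MoE interval endpoints at the low and high end of the Fue range.

    MoE increases with Fue, so the pair is (lower bound, upper bound); it
    brackets the central estimate for any Fue inside the range.
    """
    return (
        _moe_at_fue(pod, exposure_ugl, tk, population, tk.fue_low),
        _moe_at_fue(pod, exposure_ugl, tk, population, tk.fue_high),
    )


class McSummary(BaseModel):
    p5: float
    p50: float
    p95: float
    n_draws: int

    @model_validator(mode="after")
    def _ordered(self) -> "McSummary":
        if not (self.p5 <= self.p50 <= self.p95):
            raise ValueError("percentiles out of order")
        return self


def moe_mc(
    pod: PoDEntry,
    exposure_ugl: float,
    spec: UncertaintySpec,
    tk: ToxicokineticParams,
    population: Population | str = Population.adults,
) -> McSummary:
    """Empirical MoE distribution summary under triangular Fue sampling.

    Requires an explicit seed (reproducibility is part of the contract) and
    at least 100 draws for the percentile summary to be meaningful.
    Identical spec implies bit-identical output.
    """
    if spec.seed is None:
        raise ValueError("UncertaintySpec.seed must be set for Monte Carlo runs")
    if spec.n_draws < 100:
        raise ValueError("need n_draws >= 100 for percentile summaries")
    if exposure_ugl <= 0:
        raise ValueError("exposure must be strictly positive")
    rng = np.random.default_rng(spec.seed)
    if spec.fue_low == spec.fue_high:
        fues = np.full(spec.n_draws, spec.fue_mode)
    else:
        fues = rng.triangular(
            spec.fue_low, spec.fue_mode, spec.fue_high, size=spec.n_draws
        )
    # MoE is linear in fue: scale the unit-fue MoE instead of re-deriving per draw
    base = _moe_at_fue(pod, exposure_ugl, tk, population, 1.0)
    moes = base * fues
    p5, p50, p95 = np.quantile(moes, [0.05, 0.5, 0.95])
    return McSummary(p5=float(p5), p50=float(p50), p95=float(p95),
                     n_draws=spec.n_draws)
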