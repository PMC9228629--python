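"""Toxicokinetic constants and external-dose <-> urinary-concentration conversions.

The central quantity is the biomonitoring-equivalent point of departure
(HBM-PoD): the urinary metabolite concentration that corresponds, at steady
state, to an external dose at an animal point of departure (PoD).  For a
pesticide excreted in urine as a single metabolite the mass balance is

    HBM-PoD (mg/L) = PoD (mg/kg bw/day) * molar_ratio * Fue / urine_output

where ``molar_ratio`` is MW(metabolite)/MW(parent), ``Fue`` the molar urinary
excretion fraction, and ``urine_output`` the daily urinary excretion in
L/kg bw/day.  The same chain run forward converts a dietary dose into a
predicted urinary concentration; summed on a molar basis it is additive over
parent compounds that share the metabolite (chlorpyrifos and
chlorpyrifos-methyl both excrete TCPy).

Concentrations are carried internally in ug/L; mg/L appears only in the
reported (2-decimal, half-to-even) presentation values.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, Literal, Mapping, Sequence

from pydantic import BaseModel, Field, model_validator

__all__ = [
    "Population",
    "Basis",
    "Endpoint",
    "ToxicokineticParams",
    "PesticideSpec",
    "PoDEntry",
    "HBMPoD",
    "hbm_pod",
    "hbm_pod_table",
    "dose_to_urine_conc",
    "urine_conc_to_dose",
]


class Population(str, Enum):
    adults = "adults"
    children = "children"


class Basis(str, Enum):
    NOAEL = "NOAEL"
    LOAEL = "LOAEL"


class Endpoint(str, Enum):
    """Toxicological endpoints carried through the assessment.

    ``overall`` is the developmental-neurotoxicity LOAEL; the others are
    NOAELs for the stated effect.
    """

    overall = "overall"
    long_term = "long_term"
    short_term_ache = "short_term_ache"
    offspring = "offspring"
    reproductive = "reproductive"
    carcinogenicity = "carcinogenicity"


#: Table-5 style endpoint abbreviations used in roll-up reports.
ENDPOINT_ABBREV: Mapping[Endpoint, str] = {
    Endpoint.overall: "OA",
    Endpoint.long_term: "LT",
    Endpoint.short_term_ache: "ST",
    Endpoint.offspring: "OF",
    Endpoint.reproductive: "RE",
    Endpoint.carcinogenicity: "C",
}


class ToxicokineticParams(BaseModel):
    """Toxicokinetic constants for one parent pesticide.

    Fue is the molar urinary excretion fraction: the fraction of the absorbed
    parent dose recovered in urine as the metabolite, in moles.  The central
    estimate for chlorpyrifos/TCPy is 0.7 within a 0.5-0.93 range.  Two urine
    output conventions coexist and are never interchanged silently: 0.02
    (adults) / 0.03 (children) L/kg bw/day for guidance-value derivation, and
    0.024 L/kg bw/day for the food-monitoring forward model.
    """

    fue: float = 0.7
    fue_low: float = 0.5
    fue_high: float = 0.93
    molar_ratio: float = 0.566
    urine_output_adult: float = 0.02
    urine_output_child: float = 0.03
    urine_output_food_model: float = 0.024

    @model_validator(mode="after")
    def _check(self) -> "ToxicokineticParams":
        for name in (
            "fue", "fue_low", "fue_high", "molar_ratio",
            "urine_output_adult", "urine_output_child", "urine_output_food_model",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (self.fue_low <= self.fue <= self.fue_high <= 1.0):
            raise ValueError("require fue_low <= fue <= fue_high <= 1")
        if not (0.0 < self.molar_ratio < 1.0):
            raise ValueError("molar_ratio must lie in (0, 1)")
        return self

    def urine_output(self, population: Population | str) -> float:
        """Guidance-value urine output (L/kg bw/day) for a population label."""
        try:
            population = Population(population)
        except ValueError:
            raise ValueError(
                f"unknown population {population!r}; expected one of "
                f"{[p.value for p in Population]}"
            ) from None
        return (
            self.urine_output_adult
            if population is Population.adults
            else self.urine_output_child
        )


class PesticideSpec(BaseModel):
    """Identity and metabolite stoichiometry of one parent pesticide."""

    name: str
    molar_ratio: float = Field(gt=0, lt=1)
    adi_by_year: dict[int, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "PesticideSpec":
        if any(v <= 0 for v in self.adi_by_year.values()):
            raise ValueError("all ADI values must be > 0")
        return self


class PoDEntry(BaseModel):
    """One animal point of departure (mg/kg bw/day) for one endpoint."""

    endpoint: Endpoint
    value: float = Field(gt=0)
    basis: Basis
    pesticide: str = "chlorpyrifos"


class HBMPoD(BaseModel):
    """Biomonitoring-equivalent PoD: a urinary metabolite concentration.

    ``value_ugl`` keeps full precision in ug/L; ``reported_mg_l`` is the
    2-decimal mg/L presentation value, which is also the default basis for
    reported margins of exposure.
    """

    endpoint: Endpoint
    population: Population
    value_ugl: float = Field(gt=0)

    @property
    def reported_mg_l(self) -> float:
        # half-to-even at 2 decimals (mg/L), presentation only
        return round(self.value_ugl / 1000.0, 2)

    @property
    def reported_ugl(self) -> float:
        """ug/L equivalent of the rounded presentation value."""
        return self.reported_mg_l * 1000.0


def hbm_pod(
    pod: PoDEntry,
    tk: ToxicokineticParams,
    population: Population | str,
) -> HBMPoD:
    """Derive the biomonitoring-equivalent PoD for one endpoint and population.

    Applies the mass-balance conversion dose -> steady-state urinary
    concentration with the population-specific urine output (0.02 adults,
    0.03 children, L/kg bw/day).

    Parameters
    ----------
    pod
        Animal point of departure, mg/kg bw/day.
    tk
        Toxicokinetic constants of the parent pesticide.
    population
        ``"adults"`` or ``"children"``.

    Returns
    -------
    HBMPoD
        Full-precision concentration in ug/L (``reported_mg_l`` gives the
        rounded mg/L presentation value).
    """
    output = tk.urine_output(population)  # validates the population label
    population = Population(population)
    conc_mg_l = pod.value * tk.molar_ratio * tk.fue / output
    return HBMPoD(
        endpoint=pod.endpoint, population=population, value_ugl=conc_mg_l * 1000.0
    )


def hbm_pod_table(
    pods: Sequence[PoDEntry], tk: ToxicokineticParams
) -> dict[tuple[Endpoint, Population], HBMPoD]:
    """All endpoint x population biomonitoring-equivalent PoDs."""
    return {
        (pod.endpoint, pop): hbm_pod(pod, tk, pop)
        for pod in pods
        for pop in Population
    }


def dose_to_urine_conc(
    doses: Iterable[tuple[str, float]],
    molar_ratios: Mapping[str, float],
    fue: float,
    urine_output: float,
) -> float:
    """Predicted urinary metabolite concentration (ug/L) from external doses.

    Doses (mg/kg bw/day per parent pesticide) are converted to the metabolite
    mass excreted per kg bw per day via each pesticide's molar ratio and the
    shared excretion fraction, summed across pesticides, and diluted into the
    daily urine output.  Additive across pesticides by construction.
    """
    if urine_output <= 0:
        raise ValueError("urine_output must be > 0")
    total = 0.0
    for pesticide, dose in doses:
        if dose < 0:
            raise ValueError(f"negative dose for {pesticide!r}")
        try:
            ratio = molar_ratios[pesticide]
        except KeyError:
            raise ValueError(
                f"no molar ratio configured for pesticide {pesticide!r}"
            ) from None
        total += dose * ratio
    return 1000.0 * total * fue / urine_output


def urine_conc_to_dose(
    conc_ugl: float,
    pesticide: str,
    molar_ratios: Mapping[str, float],
    fue: float,
    urine_output: float,
) -> float:
    """Back-calculate the external dose (mg/kg bw/day) from a urinary level.

    Exact algebraic inverse of :func:`dose_to_urine_conc` under
    single-pesticide attribution.
    """
    if conc_ugl < 0:
        raise ValueError("concentration must be >= 0")
    try:
        ratio = molar_ratios[pesticide]
    except KeyError:
        raise ValueError(
            f"no molar ratio configured for pesticide {pesticide!r}"
        ) from None
    if ratio <= 0 or urine_output <= 0:
        raise ValueError("molar ratio and urine output must be > 0")
    return conc_ugl * urine_output / (1000.0 * ratio * fue)
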