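"""Margin-of-exposure computation and four-colour risk classification.

The margin of exposure (MoE) is the ratio of a biomonitoring-equivalent
point of departure to a measured exposure level:

    MoE(endpoint) = HBM-PoD(endpoint) / exposure

Both terms are urinary metabolite concentrations, so the MoE is
dimensionless; larger is safer.  MoEs are screened against uncertainty-factor
cutoffs into four colours:

* RED    - confirmed concern: the MoE does not cover even the standard
           inter-/intraspecies factor (100 on a NOAEL, 300 on a LOAEL,
           10,000 for carcinogenicity of a potentially genotoxic substance).
* ORANGE - possible concern: covered only when the upper range of the
           extrapolation factor is ignored; defined only for the LOAEL-based
           overall endpoint (factor up to 10 LOAEL->NOAEL) and the short-term
           AChE endpoint (factor 3 subacute->subchronic).
* YELLOW - concerns cannot be excluded: above the concern cutoffs but
           without an additional margin of 10.
* GREEN  - very low concern: at least 10x the most severe applicable
           concern threshold.

Boundary values belong to the safer class (strict ``<`` comparisons), and
classification always uses the unrounded MoE; rounding to integer happens
only in reports.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from pydantic import BaseModel, Field, model_validator

from .dosimetry import ENDPOINT_ABBREV, Endpoint, HBMPoD
from .hbm import HBMRecord, Tier

__all__ = [
    "Color",
    "ThresholdCategory",
    "CategoryThresholds",
    "ThresholdScheme",
    "MoEResult",
    "ENDPOINT_CATEGORY",
    "moe",
    "classify",
    "moe_range",
    "endpoint_rescale",
    "summarize_study",
    "default_threshold_scheme",
]


class Color(str, Enum):
    RED = "RED"
    ORANGE = "ORANGE"
    YELLOW = "YELLOW"
    GREEN = "GREEN"

    @property
    def severity(self) -> int:
        return {"RED": 3, "ORANGE": 2, "YELLOW": 1, "GREEN": 0}[self.value]


class ThresholdCategory(str, Enum):
    loael_overall = "loael_overall"
    st_ache = "st_ache"
    noael_generic = "noael_generic"
    carcinogenicity = "carcinogenicity"


#: Which cutoff category applies to each toxicological endpoint.  The
#: short-term AChE endpoint shares the long-term PoD value but carries its
#: own category because of the subacute-to-subchronic extrapolation factor.
ENDPOINT_CATEGORY: Mapping[Endpoint, ThresholdCategory] = {
    Endpoint.overall: ThresholdCategory.loael_overall,
    Endpoint.long_term: ThresholdCategory.noael_generic,
    Endpoint.short_term_ache: ThresholdCategory.st_ache,
    Endpoint.offspring: ThresholdCategory.noael_generic,
    Endpoint.reproductive: ThresholdCategory.noael_generic,
    Endpoint.carcinogenicity: ThresholdCategory.carcinogenicity,
}


class CategoryThresholds(BaseModel):
    """MoE cutoffs for one endpoint category (strict-< boundaries)."""

    red_below: float = Field(gt=0)
    orange_below: Optional[float] = None
    yellow_below: float = Field(gt=0)

    @model_validator(mode="after")
    def _ordered(self) -> "CategoryThresholds":
        if self.orange_below is not None:
            if not (self.red_below < self.orange_below < self.yellow_below):
                raise ValueError("require red_below < orange_below < yellow_below")
        elif not (self.red_below < self.yellow_below):
            raise ValueError("require red_below < yellow_below")
        return self


class ThresholdScheme(BaseModel):
    categories: dict[str, CategoryThresholds]

    def for_category(
        self, category: ThresholdCategory | str
    ) -> CategoryThresholds:
        try:
            key = ThresholdCategory(category).value
        except ValueError:
            raise ValueError(
                f"unknown endpoint category {category!r}; expected one of "
                f"{[c.value for c in ThresholdCategory]}"
            ) from None
        try:
            return self.categories[key]
        except KeyError:
            raise ValueError(f"no thresholds configured for category {key!r}") from None


def default_threshold_scheme() -> ThresholdScheme:
    """Default cutoffs.

    GREEN is operationalised as 10x the most severe applicable concern
    threshold (the orange cutoff where one exists, otherwise the red one).
    """
    return ThresholdScheme(
        categories={
            "loael_overall": CategoryThresholds(
                red_below=300, orange_below=1000, yellow_below=10_000
            ),
            "st_ache": CategoryThresholds(
                red_below=100, orange_below=300, yellow_below=3_000
            ),
            "noael_generic": CategoryThresholds(red_below=100, yellow_below=1_000),
            "carcinogenicity": CategoryThresholds(
                red_below=10_000, yellow_below=100_000
            ),
        }
    )


class MoEResult(BaseModel):
    study_id: str
    endpoint: Endpoint
    tier: Tier
    moe: float = Field(gt=0)
    color: Color

    @property
    def reported_moe(self) -> int:
        # half-to-even integer for reports; classification used full precision
        return round(self.moe)


def moe(hbm_pod: HBMPoD, exposure_ugl: float, *, use_reported: bool = True) -> float:
    """Margin of exposure for one endpoint at one exposure level.

    Parameters
    ----------
    hbm_pod
        Biomonitoring-equivalent PoD.
    exposure_ugl
        Measured urinary concentration, ug/L; must be > 0.
    use_reported
        If True (default) the 2-decimal mg/L presentation value of the
        HBM-PoD is the numerator, matching how reported MoEs are derived
        from published tables; if False, full precision is used.
    """
    if exposure_ugl <= 0:
        raise ValueError("exposure must be strictly positive")
    numerator = hbm_pod.reported_ugl if use_reported else hbm_pod.value_ugl
    return numerator / exposure_ugl


def classify(
    moe_value: float,
    endpoint_category: ThresholdCategory | str,
    scheme: ThresholdScheme | None = None,
) -> Color:
    """Map an (unrounded) MoE to a risk colour for one endpoint category."""
    if moe_value <= 0:
        raise ValueError("MoE must be strictly positive")
    scheme = scheme or default_threshold_scheme()
    cuts = scheme.for_category(endpoint_category)
    if moe_value < cuts.red_below:
        return Color.RED
    if cuts.orange_below is not None and moe_value < cuts.orange_below:
        return Color.ORANGE
    if moe_value < cuts.yellow_below:
        return Color.YELLOW
    return Color.GREEN


def moe_for_record(
    record: HBMRecord,
    hbm_pods: Mapping[Endpoint, HBMPoD],
    scheme: ThresholdScheme | None = None,
    tiers: Sequence[Tier] = (Tier.p50, Tier.p95, Tier.upper_ci),
) -> list[MoEResult]:
    """All endpoint x tier MoE results derivable from one aggregated record."""
    results = []
    for tier in tiers:
        exposure = record.tier_value(tier)
        if exposure is None:
            continue
        for endpoint, pod in hbm_pods.items():
            m = moe(pod, exposure)
            results.append(
                MoEResult(
                    study_id=record.study_id,
                    endpoint=endpoint,
                    tier=tier,
                    moe=m,
                    color=classify(m, ENDPOINT_CATEGORY[endpoint], scheme),
                )
            )
    return results


def moe_range(
    records: Iterable[HBMRecord],
    endpoint: Endpoint,
    tier: Tier,
    hbm_pods: Mapping[Endpoint, HBMPoD],
) -> tuple[float, float, list[str]]:
    """(min, max) MoE over records with the tier present, plus contributors.

    The minimum MoE is driven by the most exposed study.  Returns the
    contributing study ids in input order.
    """
    pod = hbm_pods[endpoint]
    moes: dict[str, float] = {}
    for rec in records:
        exposure = rec.tier_value(tier)
        if exposure is not None:
            moes[rec.study_id] = moe(pod, exposure)
    if not moes:
        raise ValueError(
            f"no record provides tier {tier.value!r} for endpoint {endpoint.value!r}"
        )
    return min(moes.values()), max(moes.values()), list(moes)


def endpoint_rescale(
    moe_known: float,
    from_endpoint: Endpoint,
    to_endpoint: Endpoint,
    hbm_pods: Mapping[Endpoint, HBMPoD],
) -> float:
    """Translate a known MoE to another endpoint at the same exposure.

    At fixed exposure the MoE scales with the HBM-PoD, so
    ``MoE(to) = MoE(from) * HBM-PoD(to) / HBM-PoD(from)``.  Uses the reported
    (2-decimal mg/L) PoD values, the same basis as reported MoEs.
    """
    try:
        pod_from = hbm_pods[from_endpoint]
        pod_to = hbm_pods[to_endpoint]
    except KeyError as err:
        raise ValueError(f"endpoint not available: {err.args[0]}") from None
    return moe_known * pod_to.reported_ugl / pod_from.reported_ugl


def summarize_study(
    results: Sequence[MoEResult],
) -> dict[Tier, tuple[Color, str]]:
    """Worst colour per exposure tier with the endpoints attaining it.

    For each tier present in ``results`` returns the most severe colour
    across endpoints and a label of the endpoint abbreviations at that
    colour (``"All"`` when every endpoint attains it).
    """
    if not results:
        raise ValueError("no MoE results to summarize")
    out: dict[Tier, tuple[Color, str]] = {}
    for tier in Tier:
        tier_results = [r for r in results if r.tier == tier]
        if not tier_results:
            continue
        worst = max(tier_results, key=lambda r: r.color.severity).color
        at_worst = [r.endpoint for r in tier_results if r.color == worst]
        if len(at_worst) == len(tier_results) and len(tier_results) > 1:
            label = "All"
        else:
            label = "/".join(ENDPOINT_ABBREV[e] for e in at_worst)
        out[tier] = (worst, label)
    return out
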