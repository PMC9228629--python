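"""Configuration loading: toxicokinetics, PoD sets, ADI tables, thresholds.

The packaged defaults (``data/defaults.yaml``) transcribe the published
chlorpyrifos hazard characterisation; every block can be overridden by a
user YAML with the same shape.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, Field

from .dosimetry import Basis, Endpoint, PesticideSpec, PoDEntry, ToxicokineticParams
from .risk import CategoryThresholds, ThresholdScheme

__all__ = [
    "AssessmentConfig",
    "load_default_config",
    "load_config",
    "default_hbm_fixture_path",
    "spanish_studies_fixture_path",
]


class AssessmentConfig(BaseModel):
    """Full parameter set for one assessment run."""

    toxicokinetics: ToxicokineticParams = Field(default_factory=ToxicokineticParams)
    pesticides: dict[str, PesticideSpec] = Field(default_factory=dict)
    pods: dict[str, list[PoDEntry]] = Field(default_factory=dict)
    thresholds: ThresholdScheme | None = None

    @property
    def molar_ratios(self) -> dict[str, float]:
        return {name: spec.molar_ratio for name, spec in self.pesticides.items()}

    def adi_table(self) -> dict[tuple[str, int], float]:
        return {
            (name, year): adi
            for name, spec in self.pesticides.items()
            for year, adi in spec.adi_by_year.items()
        }


def _parse(raw: dict[str, Any]) -> AssessmentConfig:
    tk = ToxicokineticParams(**raw.get("toxicokinetics", {}))
    pesticides = {
        name: PesticideSpec(name=name, **block)
        for name, block in raw.get("pesticides", {}).items()
    }
    pods = {
        name: [
            PoDEntry(
                endpoint=Endpoint(e["endpoint"]),
                value=e["value"],
                basis=Basis(e["basis"]),
                pesticide=name,
            )
            for e in entries
        ]
        for name, entries in raw.get("pods", {}).items()
    }
    thresholds = None
    if "thresholds" in raw:
        thresholds = ThresholdScheme(
            categories={
                cat: CategoryThresholds(**cuts)
                for cat, cuts in raw["thresholds"].items()
            }
        )
    return AssessmentConfig(
        toxicokinetics=tk, pesticides=pesticides, pods=pods, thresholds=thresholds
    )


def load_config(path: str | Path) -> AssessmentConfig:
    """Load an assessment configuration from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return _parse(raw)


def load_default_config() -> AssessmentConfig:
    """Packaged chlorpyrifos / chlorpyrifos-methyl defaults."""
    text = (
        resources.files("biomoe").joinpath("data/defaults.yaml").read_text()
    )
    return _parse(yaml.safe_load(text))


def default_hbm_fixture_path() -> Path:
    """Path to the packaged aggregated biomonitoring percentile table."""
    return Path(str(resources.files("biomoe").joinpath("data/hbm4eu_tcpy.csv")))


def spanish_studies_fixture_path() -> Path:
    """Path to the packaged literature-study metadata table."""
    return Path(str(resources.files("biomoe").joinpath("data/spanish_studies.csv")))
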