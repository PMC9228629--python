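import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from biomoe.config import (  # noqa: E402
    default_hbm_fixture_path,
    load_default_config,
)
from biomoe.dosimetry import Population, hbm_pod
from biomoe.hbm import read_hbm_csv, validate_records


@pytest.fixture(scope="session")
def config():
    return load_default_config()


@pytest.fixture(scope="session")
def tk(config):
    return config.toxicokinetics


@pytest.fixture(scope="session")
def pods(config):
    return {p.endpoint: p for p in config.pods["chlorpyrifos"]}


@pytest.fixture(scope="session")
def hbm_pods_by_pop(config):
    return {
        pop: {
            p.endpoint: hbm_pod(p, config.toxicokinetics, pop)
            for p in config.pods["chlorpyrifos"]
        }
        for pop in Population
    }


@pytest.fixture(scope="session")
def aligned_records():
    """The packaged aggregated biomonitoring percentile table, validated."""
    records, log = validate_records(read_hbm_csv(default_hbm_fixture_path()))
    return records, log
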