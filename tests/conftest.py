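import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from recodon.simulate import synthetic_cds_set
from recodon.usage import build_usage_table, filter_rare_codons

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def host_table():
    """A GC-rich host-like codon-usage table (71 training CDS)."""
    cds = synthetic_cds_set(71, 300, seed=11)
    table, skipped = build_usage_table(cds, source_label="host-like fixture")
    assert skipped == 0
    return table


@pytest.fixture(scope="session")
def host_allowed(host_table):
    return filter_rare_codons(host_table, 0.20)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
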