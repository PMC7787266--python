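"""Shared fixtures: one standard synthetic reference reused across tests."""

import pytest

from telocrisis.refsim import SimConfig, build_reference


@pytest.fixture(scope="session")
def std_cfg() -> SimConfig:
    """Error-free study-condition configuration for recovery tests."""
    return SimConfig(seed=101, error_rate=0.0)


@pytest.fixture(scope="session")
def std_ref(std_cfg):
    return build_reference(std_cfg)


@pytest.fixture(scope="session")
def expr_cfg() -> SimConfig:
    """Gene-dense reference for expression-linkage experiments."""
    return SimConfig(seed=303, chrom_lengths=(500_000,) * 4,
                     gene_length_mean=2000.0,
                     feature_density={"genes": 0.6, "promoters": 0.02,
                                      "enhancers": 0.02,
                                      "fragile_sites": 0.3, "ltr": 0.03})


@pytest.fixture(scope="session")
def expr_ref(expr_cfg):
    return build_reference(expr_cfg)
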