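import numpy as np
import pytest
from hypothesis import settings

from gutevolve.io_formats import load_confirmed_snps
from gutevolve.synthetic_data import (SimConfig, sample_isolates_and_reads,
                                      simulate_evolution)
from gutevolve.variant_core import filter_candidate_sites

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1_snps():
    """The bundled 22 confirmed SNPs."""
    return load_confirmed_snps()


@pytest.fixture(scope="session")
def default_sim():
    """One default-scenario simulation shared across the suite (seed 1)."""
    cfg = SimConfig(seed=1)
    truth = simulate_evolution(cfg)
    data = sample_isolates_and_reads(truth, cfg)
    return cfg, truth, data


@pytest.fixture(scope="session")
def called_default(default_sim):
    """Filter-cascade output on the default simulation."""
    _, truth, data = default_sim
    snps, gm, audit = filter_candidate_sites(data.counts, truth.genome)
    return snps, gm, audit
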