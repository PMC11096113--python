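import dataclasses

import numpy as np
import pytest

from lesionphase import simgen, mutio


SMALL_SIZES = {"chr1": 2_000_000, "chr2": 2_000_000}


@pytest.fixture(scope="session")
def small_config():
    return simgen.SimConfig(seed=101, chrom_sizes=dict(SMALL_SIZES),
                            uv_lesion_rate=2e-3, ros_rate=40.0,
                            gens_pre_split=10, gens_post_split=6)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simgen.build_genome(small_config)


@pytest.fixture(scope="session")
def default_sim():
    """One full-size (desk-scale) sister-pair simulation, shared by tests."""
    return simgen.simulate_sister_pair(simgen.SimConfig(seed=7))


@pytest.fixture(scope="session")
def default_kept(default_sim):
    kept_a, _ = mutio.filter_mutations(default_sim.calls_a)
    kept_b, _ = mutio.filter_mutations(default_sim.calls_b)
    return kept_a, kept_b


def replace(cfg, **kw):
    return dataclasses.replace(cfg, **kw)
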