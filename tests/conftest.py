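"""Shared fixtures: a reference transposase and small simulated datasets.

Everything is generated at test time from fixed seeds; module-scoped
fixtures keep the more expensive simulations shared across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from mulescan.simulate import (
    SimConfig,
    make_reference_transposase,
    simulate_genome,
)


@pytest.fixture(scope="session")
def reference():
    return make_reference_transposase(7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_sim():
    """A 10-element genome shared by discovery/nesting/pipeline tests."""
    cfg = SimConfig(seed=7, genome_len=150_000, n_elements=10)
    genome, annos, truth = simulate_genome(cfg)
    return cfg, genome, annos, truth


@pytest.fixture(scope="session")
def nested_sim():
    """A genome whose elements carry nested TE insertions."""
    cfg = SimConfig(
        seed=21,
        genome_len=200_000,
        n_elements=8,
        nested_rate=1.5,
        nested_class_mix=0.6,
    )
    genome, annos, truth = simulate_genome(cfg)
    return cfg, genome, annos, truth
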