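"""Shared fixtures: small simulated genome pairs with known ground truth.

Everything is generated at test time from fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from icrd import (
    MotifDefinition,
    SimulationConfig,
    simulate_genome_pair,
)
from icrd.synthetic_data import family_templates


SMALL_CFG = SimulationConfig(
    seed=7,
    n_chromosomes=3,
    chromosome_length=300_000,
    n_motifs=6,
    n_lone_tr=2,
    n_lone_cs=2,
)


@pytest.fixture(scope="session")
def small_sim():
    """(cfg, D-like, A-like, truth) for a 3 x 300 kb pair with 6 motifs."""
    d_like, a_like, truth = simulate_genome_pair(SMALL_CFG)
    return SMALL_CFG, d_like, a_like, truth


@pytest.fixture(scope="session")
def small_definition():
    fam = family_templates(SMALL_CFG)
    return MotifDefinition(unit_consensus=fam.unit, cs_consensus=fam.cs)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
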