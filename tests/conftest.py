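"""Shared fixtures: one synthetic study generated once per session."""

from __future__ import annotations

import pytest
from hypothesis import settings

from trfkit.seeds import ConservationIndex, ConservationRule
from trfkit.simulate import (
    SimulationConfig,
    choose_planted_windows,
    make_trna_set,
    simulate_background,
    simulate_read_libraries,
    simulate_utr_alignments,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def trna_set(sim_config):
    trnas, truth = make_trna_set(sim_config)
    return trnas, truth


@pytest.fixture(scope="session")
def trnas(trna_set):
    return trna_set[0]


@pytest.fixture(scope="session")
def read_libraries(sim_config, trnas):
    """Nine collapsed-read libraries plus planted-tRF ground truth."""
    return simulate_read_libraries(trnas, sim_config)


@pytest.fixture(scope="session")
def planted_windows(sim_config, read_libraries):
    _, truth = read_libraries
    return choose_planted_windows(truth.trfs, sim_config, n_windows=3)


@pytest.fixture(scope="session")
def utr_data(sim_config, planted_windows):
    """300 alignment blocks with 3 windows planted at k=16, plus truth."""
    return simulate_utr_alignments(sim_config, planted_windows)


@pytest.fixture(scope="session")
def utr_blocks(utr_data):
    return utr_data[0]


@pytest.fixture(scope="session")
def background(sim_config):
    return simulate_background(sim_config)


@pytest.fixture(scope="session")
def rule():
    return ConservationRule()


@pytest.fixture(scope="session")
def conservation_index(utr_blocks, rule):
    return ConservationIndex(utr_blocks, rule)
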