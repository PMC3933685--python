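"""Shared fixtures: synthetic scenarios, primers, references."""

import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from nestscan import (
    A3_F,
    A3_R,
    DegeneratePrimer,
    ScenarioConfig,
    make_species_set,
    make_splice_reference,
)
from nestscan.synthetic_data import Event


@pytest.fixture(scope="session")
def a3_primers():
    return (
        DegeneratePrimer("a3-F", A3_F, "forward"),
        DegeneratePrimer("a3-R", A3_R, "reverse"),
    )


@pytest.fixture(scope="session")
def amniote_scenario():
    """Default three-pair scenario: every host carries its nested gene."""
    cfg = ScenarioConfig(seed=101)
    return make_species_set(cfg)


@pytest.fixture(scope="session")
def frog_loss_scenario():
    """Scenario with frog-like losses: the second pair's nested gene is
    deleted (intron collapsed to 434 bp) and the third pair's host is
    deleted, plus a teleost-like tandem duplication of the free gene."""
    cfg = ScenarioConfig(
        seed=77,
        species=["human", "chicken", "frog", "coelacanth", "zebrafish", "teleost"],
        events=[
            Event("frog", "lose_nested", 1),
            Event("frog", "lose_host", 2),
            Event("teleost", "tandem_duplicate"),
        ],
    )
    return make_species_set(cfg)


@pytest.fixture(scope="session")
def splice_reference():
    return make_splice_reference(seed=0)
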