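"""Shared fixtures: a hand-built precursor profile, small synthetic
datasets and a fast experiment config for unit tests."""

import numpy as np
import pytest

from ssmirna import Dataset, ExperimentConfig, generate_two_view_dataset
from ssmirna.features import Interval, PrecursorProfile
from ssmirna.synthetic import ScenarioSpec, ViewSpec


@pytest.fixture
def toy_profile():
    """Hand-built 60-nt precursor with four read stacks (counts 50/30/15/5).

    Layout (1-based): lower stem annotated [1,4]; mature [5,24] with one
    unpaired nt (position 9); loop [25,36]; star [37,56]. Reads: an
    exact mature stack (50), an exact star stack (30), a loop stack
    starting at 26 (15), and a near-mature stack starting at 6 (5).
    """
    structure = "(" * 8 + "." + "(" * 15 + "." * 12 + ")" * 15 + "." + ")" * 8
    assert len(structure) == 60
    return PrecursorProfile(
        id="fixture_1",
        sequence="ACGU" * 15,
        structure=structure,
        mature=Interval(5, 24),
        star=Interval(37, 56),
        loop=Interval(25, 36),
        lower_stem=Interval(1, 4),
        reads=[(5, 24, 50), (37, 56, 30), (26, 35, 15), (6, 20, 5)],
        library_size=1_000_000,
    )


#: The eight expression features of ``toy_profile``, counted by hand once:
#: mature paired 19/20 -> 95%; 4 paired nts in the annotated lower stem;
#: 85/100 reads with 5' ends within 1 nt of an arm start (stacks 50+30+5),
#: so 15% Dicer-inconsistent; region read shares 55/15/30 % for
#: mature/loop/star; 100 reads in a 1e6-read library -> 100 RPM.
TOY_PROFILE_EXPECTED = np.array([95.0, 4.0, 15.0, 15.0, 55.0, 30.0, 85.0, 100.0])


@pytest.fixture
def fast_config():
    """Small forest for unit tests; protocol counts unchanged."""
    return ExperimentConfig(n_trees=25)


@pytest.fixture(scope="session")
def small_scenario():
    """A small, well-separated two-view scenario for fast end-to-end runs."""
    return ScenarioSpec(
        n_pos=40,
        n_neg=120,
        views={
            "sequence": ViewSpec(dim=6, n_informative=3, separation=1.5),
            "expression": ViewSpec(dim=5, n_informative=3, separation=2.5),
        },
        inter_view_redundancy=0.1,
        name="small",
    )


@pytest.fixture(scope="session")
def small_dataset(small_scenario) -> Dataset:
    return generate_two_view_dataset(small_scenario, np.random.default_rng(11))
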