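"""Shared fixtures: synthetic runs generated at test time (no stored data)."""

from __future__ import annotations

import pytest

from glycoridge.config import RunConfig
from glycoridge.pipeline import run_pipeline
from glycoridge.synthetic import (
    FixtureSpec,
    PlantedPeptide,
    generate_fixture,
    hagp_like_spec,
)

HAGP_SEED = 1


@pytest.fixture(scope="session")
def hagp_data():
    """The multi-site sialylated glycoprotein fixture (seed 1)."""
    return generate_fixture(hagp_like_spec(seed=HAGP_SEED))


@pytest.fixture(scope="session")
def hagp_state(hagp_data):
    """Full pipeline output on the multi-site fixture."""
    return run_pipeline(
        RunConfig(),
        hagp_data.signals,
        hagp_data.peptides,
        hagp_data.glycans,
        hagp_data.spectra,
    )


@pytest.fixture(scope="session")
def tiny_spec():
    """Two peptides x three glycoforms: the smallest end-to-end fixture."""
    return FixtureSpec(
        seed=1,
        peptides=[
            PlantedPeptide("A", 1500.7, 30.0, "P1", "10"),
            PlantedPeptide("B", 2200.9, 45.0, "P2", "20"),
        ],
        glycoforms={
            "A": [(5, 4, 0, 0), (6, 5, 0, 0), (5, 4, 1, 0)],
            "B": [(5, 4, 0, 0), (5, 4, 0, 1), (5, 4, 0, 2)],
        },
    )


@pytest.fixture(scope="session")
def tiny_data(tiny_spec):
    return generate_fixture(tiny_spec)
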