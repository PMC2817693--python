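"""Shared fixtures: a toy gene model and a small simulated genome."""

import numpy as np
import pytest
from hypothesis import settings

from cgiscape.core_io import GeneModel, GenomicInterval
from cgiscape.synthetic_data import SimulationConfig, simulate_genome

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


@pytest.fixture
def toy_gene() -> GeneModel:
    """A '+'-strand 5-exon gene with UTRs on both ends.

    tx [5000, 13000), CDS [6500, 12500), exons
    [5000,5200) [6000,6600) [7000,7300) [9000,9400) [12000,13000).
    """
    return GeneModel(
        "toy",
        "chr1",
        "+",
        5000,
        13000,
        6500,
        12500,
        tuple(
            GenomicInterval("chr1", s, e, "+")
            for s, e in [
                (5000, 5200),
                (6000, 6600),
                (7000, 7300),
                (9000, 9400),
                (12000, 13000),
            ]
        ),
    )


@pytest.fixture
def toy_gene_minus() -> GeneModel:
    """The toy gene mirrored onto the '-' strand (final exon at low coords)."""
    # mirror around 18000: x -> 18000 - x
    exons = [
        (5000, 6000),
        (8600, 9000),
        (10700, 11000),
        (11400, 12000),
        (12800, 13000),
    ]
    return GeneModel(
        "toy_minus",
        "chr1",
        "-",
        5000,
        13000,
        5500,
        11500,
        tuple(GenomicInterval("chr1", s, e, "-") for s, e in exons),
    )


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=42)


@pytest.fixture(scope="session")
def sim_genome(sim_config):
    return simulate_genome(sim_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
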