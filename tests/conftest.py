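import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cas9scan import GuideQuery, Mode
from cas9scan.fixtures import (
    PlantedSite,
    SyntheticSpec,
    generate_fixture,
    mismatch_ladder_spec,
)


def random_genome(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def random_guide(rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=20))


@pytest.fixture(scope="session")
def ladder_fixture():
    """Genome with one planted AGG-PAM site per mismatch count 0..12."""
    return generate_fixture(mismatch_ladder_spec(seed=101))


@pytest.fixture(scope="session")
def pipeline_fixture():
    """Small end-to-end dataset: gold/accessible sites plus decoys."""
    planted = (
        PlantedSite((), gold=True, accessible=True),
        PlantedSite((2,), gold=True, accessible=True),
        PlantedSite((4, 5), gold=True, accessible=True, strand="-"),
        PlantedSite((1, 7, 13), gold=True, accessible=True),
        PlantedSite((0, 10), gold=False),
        PlantedSite((3, 9, 15), gold=False, strand="-"),
        PlantedSite((6, 7, 8), gold=False),
    )
    spec = SyntheticSpec(seed=77, genome_length=6000, planted=planted, budget=9)
    return generate_fixture(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
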