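import numpy as np
import pytest

from shmrep.reference import GermlineReference, synthetic_vh_reference
from shmrep.simulate import SimulationConfig, TargetingModel


@pytest.fixture(scope="session")
def ref() -> GermlineReference:
    """The package's built-in 297-nt synthetic germline V segment."""
    return synthetic_vh_reference()


@pytest.fixture(scope="session")
def toy_ref() -> GermlineReference:
    """A 60-nt germline with simple region bounds for hand-checkable cases."""
    rng = np.random.default_rng(11)
    # stop-free 60-mer in frame 0
    codons = []
    bases = "ACGT"
    while len(codons) < 20:
        c = "".join(bases[i] for i in rng.integers(0, 4, 3))
        if c not in ("TAA", "TAG", "TGA"):
            codons.append(c)
    seq = "".join(codons)
    bounds = {
        "FR1": (0, 9),
        "CDR1": (9, 15),
        "FR2": (15, 27),
        "CDR2": (27, 33),
        "FR3": (33, 60),
    }
    return GermlineReference(name="toy", sequence=seq, region_bounds=bounds, frame_offset=0)


@pytest.fixture
def uniform_model() -> TargetingModel:
    return TargetingModel(
        hot_mutability=1.0, cold_mutability=1.0, neutral_mutability=1.0, transition_fraction=1 / 3
    )


@pytest.fixture
def hot_model() -> TargetingModel:
    return TargetingModel(
        hot_mutability=5.0, cold_mutability=0.2, neutral_mutability=1.0, transition_fraction=0.6
    )


@pytest.fixture
def small_sim_config() -> SimulationConfig:
    return SimulationConfig(
        n_clones=8,
        clone_size_law="geometric",
        clone_size_param=0.3,
        mutations_per_lineage_step=2.0,
        sequencing_error_rate=0.0,
        seed=42,
    )
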