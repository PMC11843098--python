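import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from t2tkit.genome_io import GenomeAssembly, SequenceRecord
from t2tkit.simulate import SimConfig, mutate_assembly, simulate_genome

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return BASES[rng.integers(0, 4, size=n)].tobytes().decode()


@pytest.fixture(scope="session")
def sim_pair():
    """One reference/derived assembly pair with full truth (seed 11)."""
    cfg = SimConfig(seed=11)
    ref, truth = simulate_genome(cfg)
    qry, truth = mutate_assembly(ref, truth, cfg)
    return cfg, ref, qry, truth


@pytest.fixture(scope="session")
def sim_genome():
    """A clean simulated genome with truth (seed 7), no derived assembly."""
    cfg = SimConfig(seed=7)
    genome, truth = simulate_genome(cfg)
    return cfg, genome, truth


@pytest.fixture()
def toy_assembly():
    return GenomeAssembly(
        [
            SequenceRecord("chrA", "ACGT" + "N" * 100 + "ACGT"),
            SequenceRecord("chrB", "ACGTACGT"),
        ]
    )
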