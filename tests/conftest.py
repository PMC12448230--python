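import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import haplomix as hx

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def random_reference(seed: int, L0: int, name: str = "chr") -> hx.ReferenceSequence:
    rng = np.random.default_rng(seed)
    return hx.ReferenceSequence(name, "".join(rng.choice(list("ACGT"), L0)))


@pytest.fixture
def small_reference() -> hx.ReferenceSequence:
    return random_reference(12345, 2000)


@pytest.fixture
def separable_dataset(small_reference) -> hx.SimulatedDataset:
    """Two well-separated haplotypes (elevated substitution rate), low-error
    reads: CAEM should recover the truth exactly."""
    cfg = hx.SimulationConfig(
        reference=small_reference, K=2, n_reads=80,
        evolution=[hx.EvolutionParams((0.995, 0.004, 0.001), 0.0005)] * 2,
        weights=hx.MixtureWeights((0.6, 0.4)),
        profile=1, seed=7,
        length_model=hx.LogNormalLengths(median=800, min_length=300))
    return hx.simulate_dataset(cfg)
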