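import numpy as np
import pytest

from v2g.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def noise_free_bundle():
    cfg = SyntheticConfig(
        seed=42,
        n_chromosomes=2,
        chrom_length=300_000,
        n_genes=10,
        n_signals=10,
        loop_noise_rate=0.0,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def noisy_bundle():
    cfg = SyntheticConfig(
        seed=42,
        n_chromosomes=2,
        chrom_length=300_000,
        n_genes=10,
        n_signals=10,
        loop_noise_rate=0.5,
    )
    return generate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_sequence(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
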