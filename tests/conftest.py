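import numpy as np
import pytest

from pistarve import simulate


@pytest.fixture(scope="session")
def small_config():
    """Compact study: full structure, reduced sizes so the suite stays fast."""
    return simulate.SimulationConfig(
        seed=42,
        n_mirnas=12,
        n_transcripts_per_class={
            "non-translating": 4,
            "protein-coding": 15,
            "pseudogene": 2,
            "rRNA": 4,
            "snoRNA": 2,
            "snRNA": 2,
            "SRP-RNA": 2,
            "tRNA": 3,
        },
        mean_library_size=8000,
        n_planted_targets=5,
    )


@pytest.fixture(scope="session")
def bundle_truth(small_config):
    return simulate.generate_reference(small_config)


@pytest.fixture(scope="session")
def srna_counts(small_config, bundle_truth):
    bundle, truth = bundle_truth
    return simulate.simulate_srna_counts(bundle, truth, small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_seq(rng, length):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
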