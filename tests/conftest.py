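import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

from phenolda import (  # noqa: E402
    LDAConfig,
    SyntheticSpec,
    fit_lda,
    generate_lda_phenome,
    make_block_fixture,
    to_corpus,
)

# Sampler settings used for the noisy block-diagonal fixture throughout the
# suite: with ~30 tokens per document the conventional 50/K prior mass would
# swamp the data, so a weakly informative alpha is used instead.
BLOCK_CFG = LDAConfig(
    n_topics=3, alpha=0.1, beta=0.01, n_iterations=800, burn_in=200, sample_lag=5, seed=0
)

SYNTH_CFG = LDAConfig(
    n_topics=5, alpha=0.3, beta=0.05, n_iterations=1500, burn_in=500, sample_lag=10, seed=0
)


@pytest.fixture(scope="session")
def block_truth():
    return make_block_fixture(
        n_blocks=3, drugs_per_block=20, phenos_per_block=30,
        indication_fraction=0.3, noise_rate=0.05, seed=0,
    )


@pytest.fixture(scope="session")
def block_model(block_truth):
    return fit_lda(to_corpus(block_truth.matrix), BLOCK_CFG)


@pytest.fixture(scope="session")
def synth_truth():
    return generate_lda_phenome(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def synth_model(synth_truth):
    return fit_lda(to_corpus(synth_truth.matrix), SYNTH_CFG)


@pytest.fixture(scope="session")
def block_recovery(block_truth):
    """60 masked pairs of the block fixture, recovered by full refits."""
    from phenolda import enumerate_maskable_pairs, run_recovery

    m = block_truth.matrix
    eligible = [p for p in enumerate_maskable_pairs(m) if p.eligible]
    sampler = np.random.default_rng(42)
    idx = sorted(sampler.choice(len(eligible), size=60, replace=False))
    report = run_recovery(m, BLOCK_CFG, pairs=[eligible[i] for i in idx], seed=0)
    return m, report


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
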