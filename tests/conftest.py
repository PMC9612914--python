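import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mnrelations as mn

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def chain_spec():
    """Noiseless single-study-per-pair corpus spec (exactly recoverable)."""
    return mn.SyntheticSpec(
        seed=7, sigma_log=0.0, wiring=mn.chain_wiring(), subrange=None
    )


@pytest.fixture
def noisy_globals():
    """A compact noisy corpus merged into normalized global datasets."""
    spec = mn.SyntheticSpec(seed=11, wiring=mn.compact_wiring())
    return mn.build_globals(mn.generate_corpus(spec))


@pytest.fixture
def corpus_csv(tmp_path):
    """A small synthetic corpus written to the canonical CSV schema."""
    spec = mn.SyntheticSpec(
        seed=5, wiring=mn.chain_wiring(), points_per_study=30
    )
    path = tmp_path / "corpus.csv"
    mn.save_datasets(mn.generate_corpus(spec), path)
    return path
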