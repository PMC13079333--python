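import numpy as np
import pytest

from stsforecast.preprocess import downsample_pool, normalize_per_muscle
from stsforecast.synthgen import SynthConfig, generate_corpus, generate_trial


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """Two STS cycles per strategy; fast enough for unit tests."""
    return SynthConfig(cycles_per_strategy=2, rng_seed=7)


@pytest.fixture(scope="session")
def small_trial(small_config):
    return generate_trial(small_config, "momentum")


@pytest.fixture(scope="session")
def small_corpus(small_config):
    return generate_corpus(small_config)


@pytest.fixture(scope="session")
def default_corpus():
    """The default-scale two-strategy corpus (10 cycles per strategy)."""
    return generate_corpus(SynthConfig(rng_seed=1))


def aggregated_activation(corpus, fs_out: float = 100.0):
    """Concatenate both strategies' envelopes at ``fs_out``, max-normalized.

    Returns ``(values, scale, config)`` with the per-muscle normalization
    divisors, mirroring the preprocessing conventions.
    """
    trials = list(corpus.values())
    envs = [downsample_pool(tr.true_envelopes, tr.fs, fs_out) for tr in trials]
    values, scale = normalize_per_muscle(np.concatenate(envs, axis=1))
    return values, scale, trials[0].config


@pytest.fixture(scope="session")
def default_aggregated(default_corpus):
    return aggregated_activation(default_corpus)
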