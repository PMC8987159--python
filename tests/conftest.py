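import numpy as np
import pytest

from audenc.config import demo_config
from audenc.dcae import ConvAutoencoder
from audenc.pipeline import run_pipeline
from audenc.stimulus import StimulusSpec


def sine_mixture_windows(n, length, seed):
    """Band-limited windows that a small auto-encoder can reconstruct."""
    rng = np.random.default_rng(seed)
    t = np.arange(length)
    out = np.empty((n, length))
    for i in range(n):
        f = rng.uniform(0.01, 0.2, 3)
        a = rng.uniform(0.3, 1.0, 3)
        ph = rng.uniform(0, 2 * np.pi, 3)
        x = (a[:, None] * np.sin(2 * np.pi * f[:, None] * t + ph[:, None])).sum(0)
        out[i] = 0.9 * x / np.abs(x).max()
    return out


@pytest.fixture(scope="session")
def desk_spec():
    """Desk-scale stimulation protocol: 2 kHz audio, 30-s excerpts."""
    return StimulusSpec(
        sample_rate=2000,
        tr=1.5,
        n_categories=3,
        excerpts_per_category=2,
        excerpt_duration=30.0,
        n_subjects=2,
    )


@pytest.fixture(scope="session")
def toy_windows():
    return sine_mixture_windows(240, 512, seed=0)


@pytest.fixture(scope="session")
def toy_ae(toy_windows):
    """A toy auto-encoder trained to convergence on sine mixtures."""
    return ConvAutoencoder(
        filters=(4, 8),
        filter_lengths=(16, 8),
        pool_factors=(1, 2),
        learning_rate=2e-3,
        max_epochs=200,
        patience=30,
        random_state=0,
    ).fit(toy_windows[:200])


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full desk-scale pipeline run shared across the suite."""
    out = tmp_path_factory.mktemp("demo_run")
    return run_pipeline(demo_config(seed=1), out)
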