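import numpy as np
import pytest

from vrsearch.pipeline import AnalysisConfig, process_experiment
from vrsearch.synthgen import GeneratorConfig, generate_experiment


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230331)


@pytest.fixture(scope="session")
def small_experiment():
    """Six participants, full scene design: shared across tests."""
    return generate_experiment(GeneratorConfig(n_participants=6), seed=42)


@pytest.fixture(scope="session")
def small_processed(small_experiment):
    metrics, saccades = process_experiment(small_experiment, AnalysisConfig())
    return small_experiment, metrics, saccades


@pytest.fixture(scope="session")
def clean_experiment():
    """Noise-free recording without degenerate trial types (20 trials)."""
    cfg = GeneratorConfig(
        n_participants=1, n_scenes=2, noise_sd=0.0, head_noise_sd=0.0,
        p_misclick=0.0, p_incorrect=0.0, p_no_saccade=0.0, p_first_fix=0.0,
    )
    return generate_experiment(cfg, seed=7)
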