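import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from diurnal import AnalysisConfig, GeneratorConfig, generate_transcriptome


@pytest.fixture
def rng():
    return np.random.default_rng(20260906)


@pytest.fixture(scope="session")
def default_config():
    return AnalysisConfig(seed=11)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """120-gene synthetic dataset with zero noise: exact recovery expected."""
    gen = GeneratorConfig(n_genes=120, noise_sd=0.0)
    matrix, samples, truth = generate_transcriptome(gen, seed=7)
    return matrix, samples, truth


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default-noise dataset at the study's design scale."""
    gen = GeneratorConfig(n_genes=400)
    matrix, samples, truth = generate_transcriptome(gen, seed=5)
    return matrix, samples, truth
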