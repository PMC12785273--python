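import warnings

import pytest

from epiqsar.datasets import RegulatorModule
from epiqsar.synthetic import GeneratorConfig, generate_library

warnings.filterwarnings("ignore", message=".*Stochastic Optimizer.*")


@pytest.fixture(scope="session")
def small_library():
    """A 60-compound-per-module noiseless library for fast structural tests."""
    return generate_library(GeneratorConfig(seed=11, n_per_module=60, label_noise=0.0))


@pytest.fixture(scope="session")
def benchmark_clean():
    """The default-size benchmark (250/module) without label noise."""
    return generate_library(GeneratorConfig(seed=42, n_per_module=250, label_noise=0.0))


@pytest.fixture(scope="session")
def benchmark_default():
    """The default benchmark: 250/module, 10% label noise, seed 42."""
    return generate_library(GeneratorConfig(seed=42, n_per_module=250, label_noise=0.1))


@pytest.fixture(scope="session")
def small_smiles(small_library):
    return [r.smiles_canonical for r in small_library.libraries[RegulatorModule.MIR34A]]
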