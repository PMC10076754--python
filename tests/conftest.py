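import numpy as np
import pytest

from deha_pbk import default_parameters
from deha_pbk.synthetic import GeneratorConfig, generate_study, generate_volunteer


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def noise_free_volunteer():
    """One synthetic volunteer with noise off and the dose-proportional
    adipic-acid component disabled, so every biomonitoring output is an
    exact function of the generator truth."""
    cfg = GeneratorConfig(noise=False, aa_dose_fraction=0.0)
    ds, truth = generate_volunteer(cfg, 0, seed=7)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def noisy_study():
    """A default-condition synthetic 4-volunteer study."""
    return generate_study(GeneratorConfig(), seed=42)
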