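import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from binomatch import GeneratorConfig, StimulusProtocol, generate_cohort


@pytest.fixture(scope="session")
def protocol():
    return StimulusProtocol()


@pytest.fixture(scope="session")
def noiseless_adult_cohort():
    """Small noiseless voltage-clamp cohort with ground truth."""
    cfg = GeneratorConfig.preset("adult", n_cells=3, seed=42,
                                 noise_sd=0.0)
    ds, truths = generate_cohort(cfg)
    return cfg, ds, truths


@pytest.fixture(scope="session")
def small_cc_cohort():
    """Small current-clamp cohort (low noise) with ground truth."""
    cfg = GeneratorConfig.preset("adult", clamp_mode="current_clamp",
                                 n_cells=2, seed=7, noise_sd=0.5)
    ds, truths = generate_cohort(cfg)
    return cfg, ds, truths
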