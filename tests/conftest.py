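import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20123)


@pytest.fixture
def noiseless_dataset(tmp_path):
    """Small noiseless dataset with every HC-like gene planted."""
    from motiflink.synth import SyntheticConfig, generate_dataset

    cfg = SyntheticConfig(
        n_genes=8, n_hc=4, n_pc=4, locus_length=1500,
        f_hi=1.0, f_lo=0.0,
        per_species_substitution_rate=0.0, per_species_indel_rate=0.0,
        seed=7)
    return cfg, generate_dataset(cfg, str(tmp_path / "data"))
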