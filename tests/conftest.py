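import pytest

from kernelprot.quant_io import StageDesign
from kernelprot.synthetic_data import SimConfig, simulate_quant


@pytest.fixture(scope="session")
def design() -> StageDesign:
    return StageDesign()


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Small noiseless simulated dataset with its planted truth."""
    cfg = SimConfig(n_proteins=200, noise_sigma=0.0, missing_rate=0.0, seed=11)
    records, truth = simulate_quant(cfg)
    return cfg, records, truth
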