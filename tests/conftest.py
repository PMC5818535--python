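import numpy as np
import pytest

from synucalc import simulate


@pytest.fixture(scope="session")
def titration_noiseless():
    """Noiseless titration with known ground truth (K_D=50, L=4)."""
    series, truth = simulate.generate_titration(
        seed=11, kd=50.0, ligand_number=4.0, noise=0.0
    )
    return series, truth


@pytest.fixture(scope="session")
def cest_tables():
    """CEST tables for the two calcium conditions with their truth."""
    df_no, truth_no = simulate.generate_cest(seed=3, preset="no_ca")
    df_ca, truth_ca = simulate.generate_cest(seed=4, preset="plus_ca")
    return (df_no, truth_no), (df_ca, truth_ca)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
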