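import numpy as np
import pytest

from excitedstate import synthetic_data as sd
from excitedstate.core_structures import Structure


@pytest.fixture(scope="session")
def std_fixture():
    """The standard 20-state synthetic ensemble with known ground truth."""
    return sd.standard_fixture(seed=1234)


@pytest.fixture(scope="session")
def two_regime():
    return sd.generate_two_regime_msm(n=5, m=5, k=0.01, lag=1e-6, seed=3)


def bead_structure(coords, atom_name="CA", element="C"):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    return Structure(
        elements=[element] * n,
        atom_names=[atom_name] * n,
        res_indices=np.arange(1, n + 1),
        res_names=["UNK"] * n,
        chain_ids=["A"] * n,
        coords=coords,
    )


@pytest.fixture
def refine_cfg():
    from excitedstate.eros_refine import RefinementConfig
    return RefinementConfig(theta=0.0, seed=11, max_sweeps=1500,
                            patience=150, tol=1e-12, move_scale=0.05)
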