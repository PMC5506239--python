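import numpy as np
import pytest

from nanorad import SurvivalDataset, SurvivalParams, cfu_survival


@pytest.fixture
def control_params() -> SurvivalParams:
    """Fitted parameters for unloaded cells."""
    return SurvivalParams(alpha=0.290, beta=1.9, delta=0.35, n_units=4)


@pytest.fixture
def ptnp_params() -> SurvivalParams:
    """Fitted parameters for nanoparticle-loaded cells."""
    return SurvivalParams(alpha=0.350, beta=1.9, delta=0.45, n_units=4)


@pytest.fixture
def make_noiseless_dataset():
    """Factory: exact model curve sampled on a dose grid."""

    def _make(params: SurvivalParams, doses=None, **kw) -> SurvivalDataset:
        if doses is None:
            doses = np.arange(0.0, 8.5, 0.5)
        doses = np.asarray(doses, dtype=float)
        return SurvivalDataset.from_arrays(doses, cfu_survival(doses, params), **kw)

    return _make
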