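import numpy as np
import pytest

from fishmarkers.io_meta import PeakList, SampleKey
from fishmarkers.synthetic import SyntheticConfig


@pytest.fixture
def key():
    return SampleKey("carp", "raw", 1, 1, 1)


@pytest.fixture
def pep_key():
    return SampleKey("carp", "raw", 1, 1, None)


def make_peaklist(mzs, species="carp", state="raw", individual=1, rep=1, spot=1):
    mzs = np.asarray(sorted(mzs), dtype=float)
    return PeakList(
        SampleKey(species, state, individual, rep, spot), mzs, np.ones_like(mzs)
    )


@pytest.fixture
def small_cfg():
    """Two-species config small enough for fast end-to-end tests."""
    return SyntheticConfig(
        seed=7,
        species=("carp", "salmon"),
        n_core_proteins=3,
        n_shared_proteins=2,
        n_state_proteins=1,
        protein_length=(120, 200),
    )
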