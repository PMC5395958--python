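import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from prestinlab import BoltzmannParams, GeneratorSpec
from prestinlab.synth import CL_BARRIER, SCN_BARRIER, WT_BOLTZMANN


@pytest.fixture
def wt_boltzmann() -> BoltzmannParams:
    """Wild-type NLC parameter set (Q_sp 20.32 fC/pF at C_lin 15 pF)."""
    return WT_BOLTZMANN


@pytest.fixture
def cl_barrier():
    return CL_BARRIER


@pytest.fixture
def scn_barrier():
    return SCN_BARRIER


@pytest.fixture
def short_spec() -> GeneratorSpec:
    """Generator spec with a short record for fast spectral unit tests."""
    return GeneratorSpec(seed=0, n_samples=2**17, n_channels=2000)
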