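import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from emuflux import EMU, build_emu_network, make_tca_bundle
from emuflux.datasets import INST_FRAGMENTS, STATIONARY_FRAGMENTS


@pytest.fixture(scope="session")
def tca():
    """The TCA-cycle fixture experiment (model, truth, labeling, pools)."""
    return make_tca_bundle(seed=0)


@pytest.fixture(scope="session")
def tca_net_inst(tca):
    """EMU network reaching the INST targets (full-carbon OAA and SUC)."""
    frags = tca.fragment_set(INST_FRAGMENTS)
    targets = sorted({e for f in frags for e in f.terms})
    return build_emu_network(tca.model, targets)


@pytest.fixture(scope="session")
def tca_net_stationary(tca):
    """EMU network reaching the amino-acid readout fragments."""
    frags = tca.fragment_set(STATIONARY_FRAGMENTS)
    targets = sorted({e for f in frags for e in f.terms})
    return build_emu_network(tca.model, targets)
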