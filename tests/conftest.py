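import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from zurlink.equilibria import LinkageParams
from zurlink.itc import TitrationProtocol

# EMSA conditions: 200 nM dimer, 65 nM DNA probe, zinc up to 5 uM
EMSA_P_TOTAL = 200e-9
EMSA_D_TOTAL = 65e-9
EMSA_ZINC_MAX = 5e-6


@pytest.fixture
def znua_params() -> LinkageParams:
    """znuA ladder: two dimer-sites, K_4 from ITC, K_6 = 700 K_4."""
    return LinkageParams.from_anchors(K_4=8.7e5, K_6=700 * 8.7e5, n_dna_sites=2)


@pytest.fixture
def zitb_params() -> LinkageParams:
    """zitB ladder: three dimer-sites, K_4 from ITC, K_6 = 4000 K_4."""
    return LinkageParams.from_anchors(K_4=1.8e6, K_6=4000 * 1.8e6, n_dna_sites=3)


@pytest.fixture
def zn_egta_protocol() -> TitrationProtocol:
    """2.0 mM zinc into 24 uM dimeric apo-Zur, 19 x 2 ul, 3.0 mM EGTA."""
    return TitrationProtocol(syringe_conc=2e-3, cell_macromolecule=24e-6, cell_chelator=3e-3)


@pytest.fixture
def dna_protocol() -> TitrationProtocol:
    """150 uM dimeric Zur into 3 uM DNA, 19 x 2 ul."""
    return TitrationProtocol(syringe_conc=150e-6, cell_macromolecule=3e-6)


@pytest.fixture
def zinc_grid() -> np.ndarray:
    return np.linspace(0.0, EMSA_ZINC_MAX, 26)
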