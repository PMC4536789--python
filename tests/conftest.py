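import numpy as np
import pytest

from helix3c import HelixParams, LocalChromatinParams

# Published best-fit parameter sets used across tests:
# (label, D nm, P nm, L nm/kb, Sh printed kb)
HELIX_PARAM_ROWS = [
    ("liver-gene-rich", 287.0, 160.0, 9.45, 97),
    ("wt-mesc-gene-rich", 255.0, 201.0, 9.70, 85),
    ("h1tko-gene-rich", 268.0, 230.0, 10.53, 83),
    ("h1tko-gene-poor", 269.0, 224.0, 10.53, 83),
]


@pytest.fixture
def mesc_truth():
    """Ground truth patterned on the wild-type mESC gene-rich fit."""
    return LocalChromatinParams(K=1.07, L=9.70, S=2.7), HelixParams(D=255.0, P=201.0)


@pytest.fixture
def fly_truth():
    """Ground truth patterned on fly active-chromatin virtual-3C fits."""
    return LocalChromatinParams(K=1.5, L=10.6, S=4.9)


@pytest.fixture
def rng():
    return np.random.default_rng(20150815)
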