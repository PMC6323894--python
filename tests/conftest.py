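import numpy as np
import pytest

from sweepscan.panel import HaplotypePanel


def random_panel(rng, n=8, n_sites=12, population="popA", spacing=1000,
                 maf_spectrum=None, missing_frac=0.0):
    """A small random polarized panel with segregating sites."""
    alleles = (rng.random((n, n_sites)) < rng.uniform(0.1, 0.9, size=n_sites)
               ).astype(np.int8)
    if missing_frac:
        mask = rng.random((n, n_sites)) < missing_frac
        alleles[mask] = -1
    positions = np.arange(1, n_sites + 1) * spacing
    return HaplotypePanel(alleles=alleles, positions=positions,
                          population=population)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def panel_factory():
    return random_panel
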