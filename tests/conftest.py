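import numpy as np
import pytest

from steroflip import BilayerPotential, sample_umbrella_windows

# Planted raft-like potential for the steroid with a 3-keto head group:
# barrier 6.4 kJ/mol at the midplane, 65.4 kJ/mol desorption plateau,
# equilibrium head-group position 1.7 nm.
CNONE_RAFT = dict(z_eq=1.7, dG_center=6.4, dG_desorb=65.4)


@pytest.fixture(scope="session")
def cnone_potential():
    return BilayerPotential(**CNONE_RAFT)


@pytest.fixture(scope="session")
def cnone_windows(cnone_potential):
    """One 41-window umbrella set in the planted potential (shared: costly)."""
    return sample_umbrella_windows(cnone_potential, seed=424242)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
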