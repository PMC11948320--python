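import numpy as np
import pytest
from hypothesis import settings

# fully deterministic property tests, independent of any example database
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from bcckit import examples
from bcckit.fixtures import FixtureSpec, synth_molecule


@pytest.fixture
def methane():
    return examples.methane()


@pytest.fixture
def glycol():
    return examples.ethylene_glycol()


@pytest.fixture
def benzene():
    return examples.benzene()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_molecules(n, start_seed=0, **spec_kwargs):
    """Deterministic batch of synthetic molecules for sweeps."""
    kwargs = dict(n_heavy=(3, 8), elements={"C": 5.0, "O": 2.0, "N": 1.0})
    kwargs.update(spec_kwargs)
    return [synth_molecule(FixtureSpec(seed=start_seed + k, **kwargs))
            for k in range(n)]


MOL2_METHANE = """\
@<TRIPOS>MOLECULE
methane
 5 4 1 0 0
SMALL
NO_CHARGES
@<TRIPOS>ATOM
      1 C1      0.0000   0.0000   0.0000 C.3    1 MOL 0.0000
      2 H1      0.6294   0.6294   0.6294 H      1 MOL 0.0000
      3 H2      0.6294  -0.6294  -0.6294 H      1 MOL 0.0000
      4 H3     -0.6294   0.6294  -0.6294 H      1 MOL 0.0000
      5 H4     -0.6294  -0.6294   0.6294 H      1 MOL 0.0000
@<TRIPOS>BOND
     1 1 2 1
     2 1 3 1
     3 1 4 1
     4 1 5 1
"""

XYZ_WATER = """\
3
water
O   0.000000   0.000000   0.117300
H   0.000000   0.757200  -0.469200
H   0.000000  -0.757200  -0.469200
"""
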