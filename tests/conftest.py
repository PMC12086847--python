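import warnings

import numpy as np
import pytest

from tdpbhf.fixtures import make_fixture
from tdpbhf.ground import CouplingSpec, optimize_pbhf
from tdpbhf.scf import ActiveSpace, select_active_space


@pytest.fixture(scope="session")
def h2_system():
    return make_fixture("h2").build()


@pytest.fixture(scope="session")
def lih_system():
    return make_fixture("lih").build()


@pytest.fixture(scope="session")
def h2o_system():
    return make_fixture("h2o_min").build()


@pytest.fixture(scope="session")
def synthetic_mo():
    fx = make_fixture("synthetic_orbitals")
    return fx, fx.build()


def optimize_molecular(system, lam, lambda_max=0.1, **kw):
    """PBHF state for a molecular fixture tuple at uniform coupling lam."""
    _, _, ref, mo = system
    act = select_active_space(ref, lambda_max, lam)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return optimize_pbhf(mo, CouplingSpec.uniform(act), act, ref.n_occ,
                             **kw)


def optimize_synthetic(fx, mo, lam, **kw):
    act = ActiveSpace(fx.active_indices, fx.lambda_table(lam), mo.n_mo)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return optimize_pbhf(mo, CouplingSpec.uniform(act), act, fx.n_occ,
                             **kw)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
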