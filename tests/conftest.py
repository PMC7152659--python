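import dataclasses

import numpy as np
import pytest

from halokin import RateParameters, build_mechanism, get_reference


@pytest.fixture(scope="session")
def four_step():
    return build_mechanism("four_step")


@pytest.fixture(scope="session")
def four_step_rapid():
    return build_mechanism("four_step", rapid_equilibrium_binding=True)


@pytest.fixture(scope="session")
def three_step():
    return build_mechanism("three_step")


@pytest.fixture(scope="session")
def unit_rates():
    return RateParameters(k1=1, k_minus1=1, k2=1, k3=1, k4=1, k_minus4=0)


@pytest.fixture(scope="session")
def bdp_linbwt_truth():
    """BDP/LinBwt microscopic constants with the bound-only steps pinned at
    20 s^-1, the ground truth used for synthetic single-turnover traces."""
    ref = get_reference("BDP", "LinBwt")
    return dataclasses.replace(ref.rates, k3=20.0, k4=20.0, status={})


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
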