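import copy

import pytest

from icpkpd.config import default_chains


@pytest.fixture(scope="session")
def chains():
    """Built-in typical-value configurations keyed by analyte."""
    return default_chains()


@pytest.fixture(scope="session")
def tfv(chains):
    return chains["TFV"].params


@pytest.fixture(scope="session")
def ftc(chains):
    return chains["FTC"].params


@pytest.fixture()
def tfv_cfg(chains):
    return copy.deepcopy(chains["TFV"])


@pytest.fixture()
def ftc_cfg(chains):
    return copy.deepcopy(chains["FTC"])


@pytest.fixture()
def tfv_cfg_deterministic(tfv_cfg):
    """TFV chain with all interindividual and residual variability removed."""
    tfv_cfg.variability.omega2 = {}
    tfv_cfg.variability.sigma2 = {k: 0.0 for k in tfv_cfg.variability.sigma2}
    return tfv_cfg


@pytest.fixture()
def ftc_cfg_deterministic(ftc_cfg):
    ftc_cfg.variability.omega2 = {}
    ftc_cfg.variability.sigma2 = {k: 0.0 for k in ftc_cfg.variability.sigma2}
    return ftc_cfg
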