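import numpy as np
import pytest

from phafed.model import (
    BufferSet,
    EnvCoordinate,
    HisSiteSpec,
    ModelSystem,
    SiteSpec,
)


@pytest.fixture
def glu_site():
    return SiteSpec(site_id="glu", site_class="GLU", pKa_ref=4.25)


@pytest.fixture
def glu_system(glu_site):
    """Single Glu-class compound with buffers and charge constraint."""
    return ModelSystem(sites=[glu_site], pH=4.25)


@pytest.fixture
def free_system():
    """Single unconstrained site with a decoupled environment well."""
    site = SiteSpec(site_id="g", site_class="GENERIC", pKa_ref=4.0)
    env = EnvCoordinate(min_B=0.0)
    return ModelSystem(sites=[site], envs=[env], buffers=BufferSet(count=0),
                       pH=4.0)


@pytest.fixture
def mixed_system():
    """Gated acid + multisite His: exercises every potential term."""
    sites = [
        SiteSpec(site_id="a", site_class="GLU", pKa_ref=4.25,
                 env_offset_dG=3.0, gate_height=40.0),
        HisSiteSpec(site_id="h"),
    ]
    envs = [EnvCoordinate(min_B=0.3, curv_B=150.0), EnvCoordinate(min_B=0.2)]
    return ModelSystem(sites=sites, envs=envs, pH=5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
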