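import numpy as np
import pytest

from vasokin import AcquisitionConfig, generate_aif
from vasokin.gctt import GCTTParams


@pytest.fixture(scope="session")
def config():
    """Default acquisition: 2 s DCE grid, 13 b-values, 50-echo train."""
    return AcquisitionConfig(seed=123)


@pytest.fixture(scope="session")
def aifs(config):
    return generate_aif(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def random_gctt_params(rng, n, n_agents=3):
    """Physiologically plausible tumor-voxel truths; extraction ordered by
    agent size (large dendrimer extracts least)."""
    out = []
    for _ in range(n):
        e = sorted(rng.uniform(lo, hi) for lo, hi in
                   [(0.02, 0.08), (0.10, 0.20), (0.30, 0.50)])[:n_agents]
        out.append(GCTTParams(
            v_b=rng.uniform(0.02, 0.08), t_c=rng.uniform(4.0, 15.0),
            alpha_inv=rng.uniform(0.3, 1.2), v_e=rng.uniform(0.15, 0.4),
            t_d=rng.uniform(0.5, 4.0), e=tuple(e)))
    return out
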