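import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import histocomp as hc

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg():
    """Compact cohort for unit tests (3 patients, 300 cells each)."""
    return hc.SimConfig(n_genes=400, n_cells_per_patient=300, n_patients=3,
                        cnv_segment=("chr1", 20, 220), seed=7)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return hc.simulate_scrna(small_cfg)


@pytest.fixture(scope="session")
def default_cfg():
    """Full study conditions (8 patients x 500 tumour cells)."""
    return hc.SimConfig(seed=1)


@pytest.fixture(scope="session")
def default_sim(default_cfg):
    return hc.simulate_scrna(default_cfg)


@pytest.fixture(scope="session")
def default_norm(default_sim):
    adata, _ = default_sim
    return hc.normalize_log1p(hc.apply_qc_filters(adata))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
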