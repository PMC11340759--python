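import numpy as np
import pytest

from fmtlink.pipeline import RunConfig, run_pipeline
from fmtlink.simulate import SimConfig, simulate_cohort

#: Seed of the reference cohort and golden pipeline run used across tests.
GOLDEN_SEED = 20240820


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def default_bundle():
    """The default 29-triad, 3-sub-study synthetic cohort."""
    return simulate_cohort(SimConfig(seed=GOLDEN_SEED))


@pytest.fixture(scope="session")
def small_bundle():
    """A small separable cohort for fast exact-recovery tests."""
    cfg = SimConfig(
        n_triads=8,
        n_sgb=12,
        n_donors=4,
        same_strain_dist=(0.01, 0.0),
        diff_strain_dist=(0.5, 0.0),
        seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full end-to-end run at the golden seed, shared by tests."""
    out = tmp_path_factory.mktemp("golden_run")
    cfg = RunConfig(out_dir=str(out), seed=GOLDEN_SEED)
    manifest = run_pipeline(cfg)
    return cfg, manifest
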