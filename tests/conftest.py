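from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from estkit.synthetic_data import SimConfig, simulate

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FIXTURE_SEED = 0


@pytest.fixture(scope="session")
def sim_fixture(tmp_path_factory):
    """The standard synthetic dataset: (ground truth, output dir)."""
    outdir = tmp_path_factory.mktemp("simdata")
    gt, paths = simulate(SimConfig(seed=FIXTURE_SEED), outdir)
    return gt, Path(outdir)
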