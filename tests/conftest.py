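from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from pancooc.pipeline import PipelineConfig, run_pipeline
from pancooc.simulate import default_config, generate_dataset

settings.register_profile(
    "fixed",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")

#: The study-conditions seed used by the desk-scale end-to-end fixtures.
FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic dataset: 6 strains, 5 planted + 30 background families."""
    return generate_dataset(default_config(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full simulate-mode pipeline run shared across tests."""
    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    config = PipelineConfig(mode="simulate", outdir=outdir, seed=FIXTURE_SEED)
    manifest = run_pipeline(config)
    return config, manifest, outdir
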