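import numpy as np
import pytest

from methlink.diffexpr import log_norm, size_factors
from methlink.pipeline import PipelineConfig, run_pipeline
from methlink.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One simulated cohort at the default study conditions."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def expression(default_cohort):
    _, counts, _, _, _ = default_cohort
    return log_norm(counts, size_factors(counts))


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """A full default pipeline run, shared across tests."""
    outdir = tmp_path_factory.mktemp("pipeline")
    return run_pipeline(PipelineConfig(), outdir), outdir
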