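import pytest

from orfan.pipeline import PipelineConfig, PipelineInputs, run_pipeline
from orfan.synthetic_data import SimConfig, make_metagenomes


@pytest.fixture(scope="session")
def small_sim():
    """One fully generated synthetic study, reused across tests."""
    return make_metagenomes(SimConfig(seed=7))


@pytest.fixture(scope="session")
def pipeline_report(small_sim):
    """End-to-end pipeline run on the session simulation."""
    config = PipelineConfig(seed=7, n_permutations=200)
    return config, run_pipeline(config, PipelineInputs.from_sim(small_sim))
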