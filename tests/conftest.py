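import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from polymads import pipeline as pipe
from polymads import synthetic as syn


@pytest.fixture(scope="session")
def default_genome():
    """The default study-condition genome: 20 triad units, 20 duplications."""
    return syn.generate_genome(syn.default_spec(master_seed=1))


@pytest.fixture(scope="session")
def pipeline_result(default_genome):
    """One full pipeline run on the default genome, shared across tests."""
    return pipe.run_pipeline(pipe.PipelineConfig(seed=1), genome=default_genome)
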