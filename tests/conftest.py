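import numpy as np
import pytest

from regmap.config import PipelineConfig
from regmap.pipeline import run_pipeline
from regmap.synthetic import plant_elements, simulate_genome, simulate_signal

SMALL_CLASS_COUNTS = {"coding_promoter": 20, "enhancer": 10, "inactive": 5}


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    return PipelineConfig(
        n_genes=40,
        chrom_length=400_000,
        class_counts=dict(SMALL_CLASS_COUNTS),
        seed=1,
    )


@pytest.fixture(scope="session")
def small_result(small_config):
    """One shared end-to-end run on a 400 kb fixture."""
    return run_pipeline(small_config)


@pytest.fixture(scope="session")
def small_genome():
    return simulate_genome(40, 400_000, seed=1)


@pytest.fixture(scope="session")
def small_elements(small_genome):
    return plant_elements(small_genome, dict(SMALL_CLASS_COUNTS), seed=2)


@pytest.fixture(scope="session")
def small_bundle(small_genome, small_elements):
    return simulate_signal(small_genome, small_elements, depth=50.0, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
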