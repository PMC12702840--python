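import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import phenoview as pv
from phenoview.pipeline import PipelineConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_schema() -> pv.FeatureSchema:
    """Minimal four-group schema for hand-checkable fixtures."""
    return pv.FeatureSchema(
        {
            "D": (pv.Feature("age", "numeric"),),
            "C": (
                pv.Feature("clin_a", "numeric"),
                pv.Feature("clin_b", "numeric"),
            ),
            "S_lif": (
                pv.Feature("lif_a", "categorical", ("0", "1", "2")),
                pv.Feature("lif_b", "categorical", ("0", "1")),
            ),
            "S_gen": (pv.Feature("gen_a", "categorical", ("0", "1")),),
        }
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure cohort small enough for fast unit tests."""
    table, truth = pv.generate_cohort(pv.SyntheticConfig(n=300, seed=7))
    return table, truth


@pytest.fixture(scope="session")
def medium_cohort():
    table, truth = pv.generate_cohort(pv.SyntheticConfig(n=1000, seed=11))
    return table, truth


@pytest.fixture(scope="session")
def fast_config() -> PipelineConfig:
    return PipelineConfig().fast().reseed(3)
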