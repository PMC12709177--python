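import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from dhhkit.synthetic_data import GeneratorConfig, generate_dataset
from dhhkit.workflow import run_pipeline

DEFAULT_SEED = 1234


@pytest.fixture(scope="session")
def default_dataset():
    """The synthetic default dataset (seed 1234, 20 sequences per archetype)."""
    return generate_dataset(GeneratorConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def pipeline_result(default_dataset):
    """Full pipeline run on the default dataset (computed once per session)."""
    ds = default_dataset
    return run_pipeline(
        ds.records,
        reference_id=ds.reference_id,
        signature_position=ds.signature_position,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
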