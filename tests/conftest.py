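import numpy as np
import pytest

from culturedist.pipeline import PipelineConfig, run_pipeline
from culturedist.ratings import RatingsMatrix
from culturedist.simulate import SyntheticConfig, generate_gps


@pytest.fixture(scope="session")
def study_results():
    """One full synthetic pipeline run shared by read-only tests."""
    return run_pipeline(PipelineConfig(seed=1, n_starts=4))


@pytest.fixture(scope="session")
def gps40():
    """A 40-informant GPS cohort with known competences."""
    return generate_gps(SyntheticConfig(seed=1, n_gps=40))


@pytest.fixture()
def tiny_ratings():
    values = np.array([
        [1, 2, 3, 4],
        [2, 2, 3, 4],
        [1, 3, 3, 4],
    ], dtype=float)
    return RatingsMatrix.from_arrays(values, "GPS", items=list("ABCD"))
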