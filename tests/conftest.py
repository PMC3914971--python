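import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cnasubtype as cs

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """30 samples x 60 probes: 5 strong planted parents, 2 partners each."""
    spec = cs.SyntheticSpec(
        n_pos=20,
        n_neg=10,
        p_total=60,
        informative=tuple(range(5)),
        effect_size=3.0,
        block_size=2,
        noise_sd=0.3,
        seed=7,
    )
    matrix, truth = cs.generate(spec)
    return matrix, truth


@pytest.fixture
def toy_matrix():
    """Tiny hand-written 4-sample x 3-probe matrix, two per class."""
    return cs.CNAMatrix(
        values=np.array(
            [
                [3.0, 2.0, 2.0],
                [3.1, 2.1, 1.9],
                [1.0, 2.0, 2.1],
                [1.1, 1.9, 2.0],
            ]
        ),
        sample_ids=["s1", "s2", "s3", "s4"],
        probe_ids=["p1", "p2", "p3"],
        labels=np.array(["ACA", "ACA", "SCC", "SCC"], dtype=object),
    )
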