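import numpy as np
import pytest

from beamdvh.eud import default_registry
from beamdvh.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def small_cohort():
    """Coarse-grid noiseless cohort for fast pipeline tests."""
    cfg = CohortConfig(
        n_patients=12,
        organs=("brainstem", "parotid_l"),
        dv=0.01,
        seed=3,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_quantile_curve(rng, n_bins=100, sid="brainstem", dmax=70.0):
    """Random strictly increasing quantile curve on an n_bins grid."""
    from beamdvh.dvh import DVHCurve

    increments = rng.random(n_bins) + 1e-3
    doses = np.cumsum(increments)
    doses = doses / doses[-1] * rng.uniform(0.3, 1.0) * dmax
    return DVHCurve(structure_id=sid, doses=doses, dv=1.0 / n_bins)
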