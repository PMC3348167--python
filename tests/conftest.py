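import numpy as np
import pytest

from sparsevbm.io import BrainMask, Cohort
from sparsevbm.synthetic import ClusterSpec, SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Small cohort with one direct cluster and its covarying partner."""
    clusters = [
        ClusterSpec("direct", center=(3, 3, 2), radius=1.5, kind="direct",
                    age_slope=-0.01, factor_loading=0.15),
        ClusterSpec("covary", center=(8, 8, 4), radius=1.5, kind="covarying",
                    age_slope=-0.001, factor_loading=0.1, partner="direct"),
    ]
    return SyntheticSpec(
        grid_shape=(12, 12, 6),
        n_young=20,
        n_old=20,
        noise_sd=0.05,
        latent_sd=2.0,
        smooth_fwhm_voxels=2.0,
        clusters=clusters,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture()
def separable_cohort() -> Cohort:
    """Noise-free, perfectly separable cohort: 3 label-aligned voxels among
    noise-free constant background on a tiny grid."""
    rng = np.random.default_rng(0)
    n = 20
    mask = BrainMask(in_mask=np.ones((5, 5, 2), dtype=bool))
    labels = np.array([1] * 10 + [-1] * 10)
    ages = np.concatenate([rng.uniform(18, 30, 10), rng.uniform(50, 91, 10)])
    X = 0.8 + 0.01 * rng.normal(size=(n, mask.n_voxels))
    for j in (3, 17, 30):
        X[:, j] = 0.8 + 0.2 * labels
    return Cohort(X=X, ages=ages, labels=labels, mask=mask)
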