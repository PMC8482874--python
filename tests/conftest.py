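import numpy as np
import pytest

from dnrfc import cohort as coh
from dnrfc import fc


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-subject, 12-ROI cohort used by several modules."""
    cfg = coh.CohortConfig(
        n_dnr=4, n_control=8, n_roi=12, n_timepoints=60,
        n_effect_edges=10, seed=7,
    )
    return coh.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_dynamic_fc(small_cohort):
    spec = fc.WindowSpec(window_length=40, step=2)
    return [fc.low_order_fc(s, spec) for s in small_cohort.subjects]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def complementary_signal_cohort(seed, n_per_class=30, n_features=100, shift=1.0,
                                indep_sd=0.3, n_informative=5):
    """Feature matrix with ``n_informative`` complementary informative columns.

    The informative columns share the class signal (+-shift) plus
    anti-correlated noise that sums to zero across them, so they jointly
    reconstruct the label while each carries a distinct component — a clearly
    separated two-class cohort whose signal needs all informative features.
    Columns 0..n_informative-1 are informative; the rest are pure noise.
    """
    r = np.random.default_rng(seed)
    y = np.array([1] * n_per_class + [0] * n_per_class)
    sgn = np.where(y == 1, 1.0, -1.0)
    x = r.normal(size=(2 * n_per_class, n_features))
    u = r.normal(size=(2 * n_per_class, n_informative))
    u = u - u.mean(axis=1, keepdims=True)
    x[:, :n_informative] = (
        shift * sgn[:, None] + u + indep_sd * r.normal(size=u.shape)
    )
    return x, y
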