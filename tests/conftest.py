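import numpy as np
import pytest

from netkappa import CohortSpec, RegionalTimeSeriesSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """Small but hub-structured cohort for fast end-to-end runs."""
    return CohortSpec(
        n_subjects=6,
        n_regions=30,
        n_volumes=192,
        edge_budget=90,
        kappa_targets={"RW": 0.0, "TSD": -0.5, "CSR": -0.2},
        seed=7,
    )


@pytest.fixture
def white_noise_ts(rng):
    n = 20
    return RegionalTimeSeriesSet(
        subject_id="sub-01",
        condition="RW",
        values=rng.standard_normal((n, 384)),
        region_ids=[f"R{i:03d}" for i in range(n)],
        tr_seconds=1.25,
    )


def random_correlation(n, rng):
    """Random well-conditioned correlation matrix with distinct |r| values."""
    a = rng.standard_normal((n, n + 5))
    c = a @ a.T
    d = np.sqrt(np.diag(c))
    r = c / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return r
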