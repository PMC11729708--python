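import numpy as np
import pytest

from weanling import synthetic, tooth_time


@pytest.fixture(scope="session")
def default_grid():
    return tooth_time.AgeGrid()


@pytest.fixture(scope="session")
def weaning_truth():
    """Standard-condition synthetic individual: cessation 2.0 y."""
    return synthetic.SyntheticTruth(seed=7)


@pytest.fixture(scope="session")
def weaning_profile(weaning_truth):
    df, _ = synthetic.generate_individual(weaning_truth)
    return df


@pytest.fixture(scope="session")
def binned_weaning_series():
    """Binned delta15N means of a clean decline-plateau life history
    (cessation at 2.0 y) with mild noise, on 18 half-year bin midpoints."""
    t = np.arange(0.5, 9.5, 0.5)
    rng = np.random.default_rng(42)
    y = np.where(t < 2.0, 11.5 - 2.5 / 1.5 * (t - 0.5), 9.0)
    return t, y + 0.15 * rng.standard_normal(t.size)
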