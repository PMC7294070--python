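import numpy as np
import pytest

from connclass import Dataset, FixtureSpec, SubjectTimeSeries, make_static_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_subject(rng):
    return SubjectTimeSeries("s0", rng.standard_normal((40, 8)))


@pytest.fixture
def small_cohort():
    """Two-group cohort with a strong planted effect on ten edges."""
    edges = [(i, i + 10) for i in range(10)]
    spec = FixtureSpec(
        m_per_group=15, n_rois=20, t_points=120,
        effect_edges=edges, delta_r=0.6, seed=42,
    )
    ds, truth = make_static_dataset(spec)
    return ds, truth


@pytest.fixture
def labelled_dataset(rng):
    """Minimal labelled cohort without any planted structure."""
    subs = [SubjectTimeSeries(f"s{i}", rng.standard_normal((30, 6))) for i in range(10)]
    labels = np.array([1] * 5 + [-1] * 5)
    return Dataset(subs, labels)
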