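import numpy as np
import pytest
from hypothesis import strategies as st

from scrkit import DoseVolumeHistogram


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_differential_dvh(rng, n_bins=None, max_edge=60.0):
    """Random valid differential DVH (plain numpy, for bulk property loops)."""
    n = n_bins or int(rng.integers(1, 80))
    widths = rng.uniform(0.02, max_edge / n, size=n)
    start = rng.uniform(0, 2.0)
    edges = start + np.concatenate([[0.0], np.cumsum(widths)])
    values = rng.dirichlet(np.ones(n))
    return DoseVolumeHistogram(bin_edges=edges, bin_values=values)


@st.composite
def differential_dvhs(draw, max_bins=40):
    """Hypothesis strategy for valid differential DVHs."""
    n = draw(st.integers(min_value=1, max_value=max_bins))
    widths = draw(
        st.lists(
            st.floats(0.01, 2.0, allow_nan=False, allow_infinity=False),
            min_size=n,
            max_size=n,
        )
    )
    start = draw(st.floats(0.0, 5.0, allow_nan=False))
    edges = start + np.concatenate([[0.0], np.cumsum(widths)])
    raw = np.array(
        draw(
            st.lists(
                st.floats(1e-6, 1.0, allow_nan=False, allow_infinity=False),
                min_size=n,
                max_size=n,
            )
        )
    )
    values = raw / raw.sum()
    return DoseVolumeHistogram(bin_edges=edges, bin_values=values)
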