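import numpy as np
import pytest

from picflow.io import compute_fsc_ratio, transform_intensities
from picflow.synthetic import default_panel, default_spec, simulate_cytometry


def canonical_values():
    """Five canonical 1-D distributions exercising the thresholding suite."""
    rng = np.random.default_rng(42)
    n = 20000
    return {
        "bimodal_gaussian": np.r_[rng.normal(1.0, 0.1, n // 2), rng.normal(3.0, 0.1, n // 2)],
        "skewed_unimodal": rng.lognormal(0.0, 0.6, n),
        "uniform": rng.uniform(0.0, 1.0, n),
        "two_deltas": np.r_[np.full(n // 2, 0.1), np.full(n // 2, 0.9),
                            np.array([0.0, 1.0])],  # tiny jitter ends fix the range
        "heavy_tailed": rng.standard_t(2, n),
    }


@pytest.fixture(scope="session")
def canonical():
    return canonical_values()


@pytest.fixture(scope="session")
def panel():
    return default_panel()


def prepared_events(n_events, seed, doublet_rate=0.05, confounder=False, **kw):
    """Simulated -> transformed -> ratio-derived event table."""
    spec = default_spec(doublet_rate=doublet_rate, high_scatter_confounder=confounder, **kw)
    events = simulate_cytometry(spec, n_events, seed=seed)
    events = transform_intensities(events, default_panel())
    return compute_fsc_ratio(events)


@pytest.fixture(scope="session")
def easy_events():
    """Easy-separation fixture: 4 singlet types + 5% doublets."""
    return prepared_events(20000, seed=11)


@pytest.fixture(scope="session")
def confounder_events():
    """Fixture with a high-scatter myeloid-like singlet population."""
    return prepared_events(20000, seed=12, confounder=True)
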