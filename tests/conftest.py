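import numpy as np
import pytest
from hypothesis import settings

from clubconv.panel import PanelSeries

# reproducible property tests regardless of any example database
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def closed_form_pair() -> PanelSeries:
    """N=2 panel whose log-t regressand is exactly 2*log t on the window.

    X1 = 1 + d_t, X2 = 1 - d_t with d_t = 0.5/(t log t) for t >= 2 and
    d_1 = 0.5, so H_t = d_t^2 and the regression fits with zero residuals.
    """
    T = 20
    t = np.arange(2, T + 1, dtype=float)
    d = np.concatenate([[0.5], 0.5 / (t * np.log(t))])
    return PanelSeries(units=("a", "b"), values=np.vstack([1 + d, 1 - d]))


@pytest.fixture
def diverging_pair() -> PanelSeries:
    """X1 constant, X2 linear in t: a clearly diverging pair (T=40).

    X2 = 0.6 t keeps the units distinct at every t (no degenerate H).
    """
    T = 40
    t = np.arange(1, T + 1, dtype=float)
    return PanelSeries(units=("a", "b"), values=np.vstack([np.ones(T), 0.6 * t]))


@pytest.fixture
def small_panel() -> PanelSeries:
    rng = np.random.default_rng(7)
    values = np.exp(rng.normal(size=(5, 12)) * 0.1 + 1.0)
    return PanelSeries(units=tuple("ABCDE"), values=values)
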