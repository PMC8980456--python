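import numpy as np
import pytest

from scedmed import SCEDSeries, SimulationCondition, generate_sced


def make_series(n=20, a_level=2.0, a_trend=0.2, b_path=0.59, rho=0.0, seed=0,
                noise_scale=1.0, **nuisance):
    """Complete AB series from the study generator (equal phases)."""
    cond = SimulationCondition(
        n_total=n, a_level=a_level, a_trend=a_trend, b_path=b_path, rho=rho,
        nuisance=nuisance,
    )
    return generate_sced(cond, seed=seed, noise_scale=noise_scale)


@pytest.fixture
def series20():
    return make_series(n=20, seed=42)


@pytest.fixture
def series_linear():
    """Strong linear signal, low noise: imputation diagnostics stay tight."""
    return make_series(n=40, a_level=4.0, a_trend=0.3, b_path=1.0, seed=7,
                       noise_scale=0.5, b1M=0.2, b1Y=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
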