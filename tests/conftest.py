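import numpy as np
import pytest

from joinprod.simulate import PopulationParameters, simulate_series


@pytest.fixture(scope="session")
def low_noise_series():
    """Deterministic-ish recovery benchmark: big regime change, tiny noise."""
    params = PopulationParameters(
        r1=0.8, r2=0.3, q1=1.5e-5, q2=2.5e-5, catch_noise_var=1e-4
    )
    series = simulate_series(params, np.random.default_rng(7))
    return params, series
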