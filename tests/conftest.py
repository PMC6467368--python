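import pytest

from breechcea import default_parameters, evaluate_strategy, point_draw
from breechcea.psa import run_psa

PSA_SEED = 12345
PSA_N = 100_000


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def psa_samples(params):
    """One full-size PSA shared across the session."""
    return run_psa(params, PSA_N, seed=PSA_SEED)


@pytest.fixture(scope="session")
def point_results(params):
    """Deterministic evaluation of both arms at point estimates."""
    draw = point_draw(params)
    return {s: evaluate_strategy(s, draw, params.econ) for s in ("universal", "selective")}
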