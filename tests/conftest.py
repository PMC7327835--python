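import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20201)


@pytest.fixture
def tiny_model():
    """A small three-scale population for fast end-to-end tests."""
    from threeform.simulation import PopulationModel

    sizes = {"s1": 6, "s2": 6, "s3": 7}
    scales = {sid: tuple(f"{sid}_i{k}" for k in range(P)) for sid, P in sizes.items()}
    loadings = {sid: np.linspace(0.5, 0.8, P) for sid, P in sizes.items()}
    return PopulationModel(
        scales=scales,
        loadings=loadings,
        intercepts={sid: np.full(P, 3.0) for sid, P in sizes.items()},
        residual_variances={sid: 1.0 - loadings[sid] ** 2 for sid in sizes},
        latent_corr=np.array([[1.0, 0.4, 0.2], [0.4, 1.0, 0.3], [0.2, 0.3, 1.0]]),
        extant_rate=0.0,
    )
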