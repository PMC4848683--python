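import numpy as np
import pytest
from hypothesis import settings

from tumorkinetics.config import CohortConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def make_config():
    """Factory for cohort configs; kwargs override the study defaults."""

    def _make(**overrides) -> CohortConfig:
        return CohortConfig(**overrides)

    return _make


@pytest.fixture
def small_config():
    """A reduced cohort (~20 tumors/strain) for fast Monte-Carlo loops."""

    def _make(seed: int = 0, **overrides) -> CohortConfig:
        base = dict(
            seed=seed,
            n_rats_per_strain={"DR": 10, "DS": 10},
            incidence={"DR": 1.0, "DS": 1.0},
            multiplicity_mean={"DR": 2.0, "DS": 2.0},
        )
        base.update(overrides)
        return CohortConfig(**base)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20160411)


def nb_draws(rng, mean: float, k: float, size: int) -> np.ndarray:
    """Gamma-mixed Poisson draws: the NB family the count models assume."""
    return rng.poisson(rng.gamma(k, mean / k, size))
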