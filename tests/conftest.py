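import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bayesrd import CohortConfig, PriorSpec, RDDataset, generate_cohort
from bayesrd.sampling import SamplerSettings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sampler() -> SamplerSettings:
    """Modest chain settings for unit tests; enough for ~1e-2 MC error."""
    return SamplerSettings(chains=2, warmup=500, draws=1000, seed=0)


@pytest.fixture(scope="session")
def strong_cohort():
    """One strong-instrument, low-confounding cohort (true reduction 2 mmol/l)."""
    data, truth = generate_cohort(CohortConfig(n=2000, seed=42))
    return data, truth


@pytest.fixture()
def toy_dataset() -> RDDataset:
    rng = np.random.default_rng(0)
    x = rng.uniform(0, 0.4, size=60)
    z = (x >= 0.2).astype(int)
    t = z.copy()
    y = 3.0 + 1.5 * (x - 0.2) - 2.0 * t + rng.normal(0, 0.3, size=60)
    return RDDataset(x=x, t=t, y=y, x0=0.2)


@pytest.fixture(scope="session")
def default_prior() -> PriorSpec:
    return PriorSpec.preset("sip", "fdp")
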