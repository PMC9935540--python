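import numpy as np
import pytest

import clawfsa as c


@pytest.fixture(scope="session")
def small_claw():
    """A coarse curved claw used wherever geometry details don't matter."""
    return c.generate_claw_mesh(
        c.ClawParams(axial_segments=8, circumferential_segments=4, seed=3)
    )


@pytest.fixture(scope="session")
def medium_claw():
    return c.generate_claw_mesh(
        c.ClawParams(axial_segments=16, circumferential_segments=6, seed=1)
    )


@pytest.fixture(scope="session")
def material():
    return c.MaterialSpec()


def random_field(seed: int, n: int = 500, mean: float = 8.0, sigma: float = 0.5,
                 specimen_id: str = "spec", scenario: str = "piercing") -> c.StressField:
    g = np.random.default_rng(seed)
    mu = np.log(mean) - sigma**2 / 2
    return c.StressField(
        g.lognormal(mu, sigma, n), g.uniform(0.5, 2.0, n), scenario, specimen_id
    )
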