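import numpy as np
import pytest

from apcie import APCTable, SyntheticSpec, simulate


@pytest.fixture
def constant_table() -> APCTable:
    """5x4 grid with the same rate (20 per 100,000) in every cell."""
    a, p = 5, 4
    return APCTable(
        deaths=np.full((a, p), 20.0),
        exposures=np.full((a, p), 1e5),
        age_starts=10 + 5 * np.arange(a),
        period_starts=1985 + 5 * np.arange(p),
    )


@pytest.fixture
def study_grid_table() -> APCTable:
    """A 14x6 grid on the 1985-2010 / ages 10-79 layout (19 cohorts)."""
    spec = SyntheticSpec(a=14, p=6, exposures=1e6, seed=11)
    return simulate(spec)


def random_spec(rng: np.random.Generator, a: int, p: int,
                exposure: float = 1e5) -> SyntheticSpec:
    """A random smooth-ish effect structure on an a x p grid."""
    def curve(n):
        x = rng.normal(scale=0.3, size=n)
        return x - x.mean()

    return SyntheticSpec(
        a=a, p=p,
        alpha=curve(a), beta=curve(p), gamma=curve(a + p - 1),
        exposures=exposure,
        seed=int(rng.integers(2**31)),
    )
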