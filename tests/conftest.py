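import numpy as np
import pytest
from scipy import special

from pfasquant import synth
from pfasquant.registry import load_default_registry


@pytest.fixture(scope="session")
def registry():
    return load_default_registry()


@pytest.fixture(scope="session")
def noiseless_study(registry):
    """Noiseless replicate study: areas are exactly rf x on-column amount."""
    design = synth.StudyDesign()
    response = synth.ResponseModel.flat(registry, rf=1000.0, rho=0.0)
    noise = synth.NoiseModel(area_cv=0.0, area_floor=0.0)
    areas, truth = synth.simulate_replicate_study(design, registry, response, noise, seed=11)
    return design, areas, truth


def t_quantile_oracle(df: int, q: float, tol: float = 1e-12) -> float:
    """Student-t quantile by bisecting the incomplete-beta CDF.

    Independent of scipy.stats.t: uses only the regularized incomplete beta
    function, F(t) = 1 - I_{df/(df+t^2)}(df/2, 1/2) / 2 for t >= 0.
    """
    assert 0.5 <= q < 1

    def cdf(t: float) -> float:
        if t < 0:
            return 1.0 - cdf(-t)
        x = df / (df + t * t)
        return 1.0 - 0.5 * special.betainc(df / 2.0, 0.5, x)

    lo, hi = 0.0, 1.0
    while cdf(hi) < q:
        hi *= 2
    while hi - lo > tol * max(1.0, hi):
        mid = 0.5 * (lo + hi)
        if cdf(mid) < q:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
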