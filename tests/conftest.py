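import numpy as np
import pytest

from hospflow import ModelParams, REFERENCE_PARAMS


@pytest.fixture
def ref_params() -> ModelParams:
    """Parameter vector estimated from the national 2011-2018 series."""
    return REFERENCE_PARAMS


def random_params(rng: np.random.Generator, min_margin: float = 0.0) -> ModelParams:
    """Draw a random valid parameter set spanning all stability regimes.

    Rates are log-uniform at monthly scales; capacities span two
    orders of magnitude.  With ``min_margin`` > 0 the draw is rejected
    until every H-condition holds with at least that absolute margin,
    keeping the set away from the boundary hypersurfaces (where
    classification is legitimately marginal and convergence is slow).
    """
    while True:
        r = 10.0 ** rng.uniform(-1.7, -0.3, 3)
        m = 10.0 ** rng.uniform(2.0, 4.5, 3)
        c = 10.0 ** rng.uniform(-3.0, -0.7, 3)
        tr = 10.0 ** rng.uniform(-2.5, -1.0, 3)
        p = ModelParams(
            r_f=r[0], r_s=r[1], r_t=r[2],
            m_f=m[0], m_s=m[1], m_t=m[2],
            c_f=c[0], c_s=c[1], c_t=c[2],
            alpha=tr[0], beta=tr[1], eta=tr[2],
        )
        margins = (
            abs(p.r_t - p.c_t),
            abs(p.r_s - p.beta - p.c_s),
            abs(p.r_f - p.alpha - p.eta - p.c_f),
        )
        if min(margins) >= min_margin:
            return p


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220426)
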