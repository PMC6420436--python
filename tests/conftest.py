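import numpy as np
import pandas as pd
import pytest

from repmod import GenParams, ModelSpec, WideDataset, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def hand_fit_data():
    """Tiny regression fixture with hand-computed normal-equation results.

    Centered W = (-1.5, -0.5, 0.5, 1.5), Y_D = (0, 1, 2, 4):
    b0 = mean(Y) = 1.75, b1 = Sxy/Sxx = 6.5/5 = 1.3, SSE = 0.30, df = 2,
    sigma2 = 0.15, var(b1) = 0.15/5 = 0.03, var(b0) = 0.15/4 = 0.0375.
    """
    w = np.array([-1.0, 0.0, 1.0, 2.0])
    y_d = np.array([0.0, 1.0, 2.0, 4.0])
    d = WideDataset(
        y1=y_d, y2=np.zeros(4), moderators=pd.DataFrame({"w": w})
    )
    expected = {
        "b": (1.75, 1.3),
        "sse": 0.30,
        "df": 2,
        "sigma2": 0.15,
        "var_b1": 0.03,
        "var_b0": 0.0375,
    }
    return d, expected


@pytest.fixture
def pain_like_dataset():
    """A pre/post study-shaped dataset: n=40, one continuous moderator."""
    return generate(GenParams(seed=11))


def random_dataset(rng, n=30, m=1, multiplicative=False, sigma=1.0, rho=0.3):
    """Random small fixture with distinct per-condition coefficients."""
    ncoef = 2**m if multiplicative else m + 1
    params = GenParams(
        n=n,
        b_cond1=tuple(rng.normal(0, 1, ncoef)),
        b_cond2=tuple(rng.normal(0, 1, ncoef)),
        sigma1=sigma,
        sigma2=sigma,
        rho=rho,
        moderator_dists=tuple(("normal", 0.0, 1.0) for _ in range(m)),
        seed=int(rng.integers(2**31 - 1)),
    )
    return generate(params), params


@pytest.fixture
def simple_spec():
    return ModelSpec(model_type="multiplicative", center=False)
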