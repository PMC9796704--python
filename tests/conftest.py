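import numpy as np
import pytest

from spomdyn.kernel import DispersalParams, ExtinctionParams, ModelSpec
from spomdyn.network import DetectionHistory, PatchNetwork
from spomdyn.params import DetectionParams, SPOMParameters
from spomdyn.simulate import ScenarioConfig


@pytest.fixture
def three_patch_network():
    return PatchNetwork(
        patch_id=["a", "b", "c"],
        x=[0.0, 1.0, 0.3],
        y=[0.0, 0.2, 1.1],
        length=[0.5, 1.2, 0.8],
    )


@pytest.fixture
def two_patch_network():
    return PatchNetwork(patch_id=["p1", "p2"], x=[0.0, 1.0], y=[0.0, 0.0], length=[1.0, 1.0])


def make_params(
    psi1=0.5,
    delta0=0.5,
    delta1=-2.0,
    alpha=0.5,
    beta=0.15,
    sigma_alpha=0.0,
    sigma_beta=0.0,
    mu_p=1.4,
    sigma_p=0.3,
    **kw,
):
    return SPOMParameters(
        psi1=psi1,
        extinction=ExtinctionParams(delta0, delta1),
        dispersal=DispersalParams(
            alpha=alpha, beta=beta, sigma_alpha=sigma_alpha, sigma_beta=sigma_beta, **kw
        ),
        detection=DetectionParams(mu_p=mu_p, sigma_p=sigma_p),
    )


def make_scenario(
    n=20,
    T=8,
    extent=(8.0, 6.0),
    model=ModelSpec(weighted=True),
    visits=(3, 3),
    missing_rate=0.0,
    seed=0,
    **param_kw,
):
    return ScenarioConfig(
        n_patches=n,
        extent=extent,
        length_dist=(0.05, 3.0, 0.847),
        T=T,
        params=make_params(**param_kw),
        model=model,
        visits=visits,
        missing_rate=missing_rate,
        seed=seed,
    )


@pytest.fixture
def tiny_history(three_patch_network):
    """3 patches x 3 years x <=2 visits with detections, zeros and gaps."""
    y = np.full((3, 3, 2), np.nan)
    y[0, 0, :] = [1, 0]
    y[1, 0, 0] = 0
    y[2, 0, :] = [0, 0]
    y[0, 1, 0] = 0
    y[1, 1, :] = [1, 1]  # patch c unsurveyed in year 1
    y[0, 2, :] = [0, 1]
    y[1, 2, 0] = 0
    y[2, 2, 0] = 1
    return DetectionHistory(y=y, years=np.arange(3))
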