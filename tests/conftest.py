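import numpy as np
import pytest

from atnfit.foodweb import FoodWeb, Guild, RateParameters


@pytest.fixture
def three_node_web() -> FoodWeb:
    """Producer -> consumer, consumer -> detritus; detritivory closes the loop."""
    guilds = [
        Guild("alga", "producer"),
        Guild("grazer", "consumer", max_body_mass=10.0, has_catch=True),
        Guild("detritus", "detritus"),
    ]
    links = [("grazer", "alga"), ("grazer", "detritus")]
    e = {("grazer", "alga"): 0.66, ("grazer", "detritus"): 0.45}
    return FoodWeb(guilds, links, e=e, s={"alga": 0.2}, ua={"grazer": 0.8})


@pytest.fixture
def three_node_params(three_node_web) -> RateParameters:
    return RateParameters(
        r=np.array([1.5]),
        K=10.0,
        um=np.array([0.4]),
        J=np.array([2.0, 0.5]),
        B0=np.array([3.0, 4.0]),
        q=np.array([0.2, 0.0]),
        um_lower=np.array([0.1]),
    )


@pytest.fixture
def three_node_state() -> np.ndarray:
    return np.array([6.0, 2.0, 5.0])
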