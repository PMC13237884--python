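import numpy as np
import pandas as pd
import pytest

from psmkit.io_cli import load_packaged_config
from psmkit.km_tools import PseudoIPD
from psmkit.survdist import ParametricSurvival
from psmkit.synthetic_data import make_toy_config


@pytest.fixture(scope="session")
def toy_config():
    return make_toy_config(seed=0)


@pytest.fixture(scope="session")
def overall_config():
    return load_packaged_config("overall")


@pytest.fixture(scope="session")
def weibull_ipd():
    """n=300 Weibull event times, administratively censored at 36 months."""
    dist = ParametricSurvival("weibull", (20.0, 1.2), "months")
    t = dist.sample(300, seed=42)
    cap = 36.0
    return PseudoIPD(
        pd.DataFrame({"time": np.minimum(t, cap), "event": (t <= cap).astype(int)}),
        arm="sim",
        endpoint="PFS",
    )
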