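import numpy as np
import pytest
from hypothesis import settings

import gaswash as gw

settings.register_profile("repro", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def agents():
    return gw.default_agents()


@pytest.fixture(scope="session")
def body():
    return gw.default_body()


@pytest.fixture(scope="session")
def iso(agents):
    return agents["isoflurane"]


@pytest.fixture(scope="session")
def sevo(agents):
    return agents["sevoflurane"]


@pytest.fixture(scope="session")
def des(agents):
    return agents["desflurane"]


@pytest.fixture(scope="session")
def study_result():
    """The full 3 x 2 x 6 emergence study, simulated once per session."""
    return gw.run_study(keep_traces=True)


def make_timeseries(t, f_vrg, **overrides):
    """Synthetic TimeSeries for metric tests: every column defaults to
    zeros except the supplied ones."""
    t = np.asarray(t, dtype=float)
    z = np.zeros_like(t)
    cols = dict(f_d=z, fgf=z, v_a=z, f_i=z, f_a=z,
                f_vrg=np.asarray(f_vrg, dtype=float),
                f_mus=z, f_fat=z, f_mv=z)
    cols.update({k: np.asarray(v, dtype=float) for k, v in overrides.items()})
    return gw.TimeSeries(t=t, **cols)
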