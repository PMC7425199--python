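import numpy as np
import pytest

from mouseatria import ModelParameters, core


@pytest.fixture(scope="session")
def params():
    return ModelParameters.default()


@pytest.fixture(scope="session")
def warm_state(params):
    """Shipped paced-in end-diastolic snapshot (1-Hz history)."""
    return core.default_initial_state(params)


@pytest.fixture(scope="session")
def steady_05hz(params, warm_state):
    """End-diastolic state after settling at 0.5-Hz pacing."""
    res = core.pace_beats(warm_state, params, 2000.0, 40, record=False)
    return res.final_state


@pytest.fixture(scope="session")
def steady_2hz(params, warm_state):
    """End-diastolic state after settling at 2-Hz pacing."""
    res = core.pace_beats(warm_state, params, 500.0, 40, record=False)
    return res.final_state


@pytest.fixture(scope="session")
def beat_05hz(params, steady_05hz):
    """One fully recorded steady beat at 0.5 Hz."""
    return core.pace_beats(steady_05hz, params, 2000.0, 1)


@pytest.fixture(scope="session")
def beat_2hz(params, steady_2hz):
    return core.pace_beats(steady_2hz, params, 500.0, 1)


def total_cell_ca(y, params):
    """Volume-weighted total Ca2+ (free + buffered, all compartments)."""
    v = params.volumes()
    free = (y[core.ICAI] * v["cyto"] + y[core.ICASL] * v["SL"]
            + y[core.ICACLEFT] * v["cleft"] + y[core.ICASR] * v["SR"])
    bound = ((y[core.ITNC] + y[core.ICAMB] + y[core.ISRB]) * v["cyto"]
             + (y[core.ISLL_SL] + y[core.ISLH_SL]) * v["SL"]
             + (y[core.ISLL_CL] + y[core.ISLH_CL]) * v["cleft"]
             + y[core.ICSQN] * v["SR"])
    return free + bound
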