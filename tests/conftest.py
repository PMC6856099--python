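import numpy as np
import pytest

import infoseek as ik
from infoseek.synthetic_data import GazeBehaviorSpec


@pytest.fixture(scope="session")
def plain_gaze():
    return GazeBehaviorSpec()


@pytest.fixture(scope="session")
def attracted_gaze():
    return ik.uncertainty_attracted_gaze_spec()


@pytest.fixture(scope="session")
def std_session(plain_gaze):
    """Uncertainty-tuned standard-task session (no gaze modulation)."""
    spec = ik.uncertainty_neuron_spec()
    return ik.gen_uncertainty_session(spec, plain_gaze, 20, seed=101)


@pytest.fixture(scope="session")
def modulated_session(plain_gaze):
    """Gaze-gain-modulated standard-task session."""
    spec = ik.uncertainty_neuron_spec(w_gain=1.0, mu=0.2, sigma=0.1)
    return ik.gen_uncertainty_session(spec, plain_gaze, 30, seed=102)


@pytest.fixture(scope="session")
def info_session_h1(attracted_gaze):
    """Hypothesis-1 (information-anticipating) information-task session."""
    spec = ik.info_neuron_spec(hypothesis=1)
    return ik.gen_info_session(spec, attracted_gaze, 40, seed=103)


def roc_brute_force(x, y):
    """Exhaustive pairwise-comparison ROC oracle (wins + half-ties)."""
    wins = sum(1.0 for a in x for b in y if a > b)
    ties = sum(1.0 for a in x for b in y if a == b)
    return (wins + 0.5 * ties) / (len(x) * len(y))
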