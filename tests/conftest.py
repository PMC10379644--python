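import numpy as np
import pytest

from listeneff import design, lba, synthetic


@pytest.fixture(scope="session")
def table_params() -> lba.LBAParams:
    """Natural-scale parameters anchored to the published NH group means."""
    truth = design.default_ground_truth()
    return synthetic.params_from_vector(np.exp(truth.log_mean["NH"]))


@pytest.fixture(scope="session")
def ci_params() -> lba.LBAParams:
    truth = design.default_ground_truth()
    return synthetic.params_from_vector(np.exp(truth.log_mean["CI"]))


@pytest.fixture(scope="session")
def small_trials():
    """A compact simulated dataset: 3+3 participants, full 168-trial
    schedule each, with the default ground truth."""
    truth = design.default_ground_truth()
    spec = design.DesignSpec(n_group_a=3, n_group_b=3)
    schedule = design.build_design(spec, seed=11)
    params = synthetic.draw_participants(truth, spec, seed=12)
    trials = synthetic.simulate_behavior(schedule, params, deadline=3.0, seed=13)
    return trials, params, spec, truth
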