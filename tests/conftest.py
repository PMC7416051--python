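import numpy as np
import pandas as pd
import pytest

from meridian import synthetic


@pytest.fixture(scope="session")
def desk_spec():
    return synthetic.DESK_SPEC


@pytest.fixture(scope="session")
def desk_design_pair(desk_spec):
    return synthetic.generate_design_pair(desk_spec, seed=11)


@pytest.fixture(scope="session")
def behavior_record(desk_design_pair):
    seq = pd.concat(desk_design_pair, ignore_index=True)
    params = synthetic.BehaviorParams(seed=5)
    return synthetic.generate_behavior(seq, params)


@pytest.fixture(scope="session")
def desk_truth():
    return synthetic.default_ground_truth(snr=1.0)


@pytest.fixture(scope="session")
def desk_bold(desk_design_pair, desk_truth, desk_spec):
    bold, inputs = synthetic.generate_bold(
        desk_design_pair, desk_truth, spec=desk_spec, seed=3
    )
    return bold, inputs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
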