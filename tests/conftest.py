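import numpy as np
import pytest

import robnet as rn
from robnet.cases import build_case

UNIT_SRNA_PARAMS = {
    "c1": {"value": 1.0}, "c2": {"value": 1.0},
    "b11": {"value": 1.0}, "b22": {"value": 1.0},
    "b12": {"slope": 1.0},
}

#: closed-form equilibrium of the unit sRNA instance: 1 - x - x^2 = 0
GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@pytest.fixture(scope="session")
def srna_model():
    return rn.load_packaged_model("srna")


@pytest.fixture(scope="session")
def unit_srna(srna_model):
    cfg = rn.SamplingConfig(term_params=UNIT_SRNA_PARAMS)
    inst = rn.sample_instance(srna_model, cfg, seed=0)
    field = rn.assemble_rhs(srna_model, inst)
    return srna_model, inst, field


@pytest.fixture(scope="session")
def cases():
    cache = {}

    def get(name):
        if name not in cache:
            cache[name] = build_case(name)
        return cache[name]
    return get
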