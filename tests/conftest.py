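import pandas as pd
import pytest

from fermstoich.chem_core import default_registry
from fermstoich.community_response import AbundanceTable, SampleMeta


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture()
def hand_table():
    """Four-sample hand example for the three-step net-increase procedure.

    Treatment 'glu' (pooled) goes 2% -> 10% for ptA while the control
    (pooled here for arithmetic simplicity) goes 3% -> 4%; filler taxa absorb
    the rest of each composition.
    """
    data = pd.DataFrame(
        {
            "glu_t0": [0.02, 0.50, 0.48],
            "glu_t1": [0.10, 0.46, 0.44],
            "ctl_t0": [0.03, 0.50, 0.47],
            "ctl_t1": [0.04, 0.495, 0.465],
        },
        index=["ptA", "ptB", "ptC"],
    )
    samples = {
        "glu_t0": SampleMeta("glu", "t0", "DNA", None),
        "glu_t1": SampleMeta("glu", "t_end", "DNA", None),
        "ctl_t0": SampleMeta("control", "t0", "DNA", None),
        "ctl_t1": SampleMeta("control", "t_end", "DNA", None),
    }
    return AbundanceTable(data, samples)
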