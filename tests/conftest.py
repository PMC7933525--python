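import numpy as np
import pytest

from nmnsd import NMNSDStructure, NeuronParams, ParallelSpikeTrain


@pytest.fixture
def params04():
    """Shared neuron parameters at the recommended operating point:
    S_th = 1.04 (ttf_max = 25 ms), linear decay 0.05/ms."""
    return NeuronParams.from_threshold(1.04, Ld=0.05)


@pytest.fixture
def two_branch(params04):
    """The worked two-branch detector: input weights (1.08, 1.10), equal
    output weights 0.6 (sum 1.2 >= S_th, single-crossing guarantee holds)."""
    return NMNSDStructure(np.array([1.08, 1.10]), np.array([0.6, 0.6]),
                          delay_params=params04, target_params=params04)


def make_structure(w_in, w_out, Ld=0.05, Sth=1.04):
    p = NeuronParams.from_threshold(Sth, Ld=Ld)
    return NMNSDStructure(np.asarray(w_in, float), np.asarray(w_out, float),
                          delay_params=p, target_params=p)


def train_of(*times):
    return ParallelSpikeTrain(np.array(times, dtype=float))
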