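# nmnsd — spiking-neuron classification of parallel spike trains

`nmnsd` implements a spiking-neuron classifier for *parallel spike
trains* — patterns of one spike per input channel, described by their
relative timing.  It is aimed at computational neuroscientists and
engineers who want a compact, fully event-driven, online-learning
temporal classifier: latency features extracted from multichannel
recordings, latency-encoded images, or any feature vector mapped to
first-spike times.

## The model

The neuron is a **LIFL** (leaky integrate-and-fire with latency).  Its
state *S* decays linearly below the threshold *S*<sub>th</sub> = 1 + *d*
(rate *L*<sub>d</sub> per ms, floored at the resting value
*S*<sub>0</sub> = 0) and, once *S* ≥ *S*<sub>th</sub>, the neuron fires
after a state-dependent latency

&nbsp;&nbsp;&nbsp;&nbsp;*ttf* = 1/(*S* − 1),&nbsp;&nbsp;&nbsp;
*ttf*<sub>max</sub> = 1/*d*.

With the recommended *S*<sub>th</sub> = 1.04 the latency spans up to
25 ms, and a drive of 1.08 sits at mid-range (12.5 ms).

An **nMNSD structure** of order *n* chains three weight sets around this
latency mechanism:

- *input weights* `w_in` turn each branch's drive into a programmable
  delay 1/(*A*·`w_in[i]` − 1) via a per-branch *delay neuron*;
- *output weights* `w_out` feed the delayed spikes to a single readout
  *target neuron*, which fires when enough contributions arrive nearly
  simultaneously (the *simultaneity condition*);
- *heterosynaptic weights* (≈0) between adjacent delay neurons mediate
  the learning signal.

The relative input intervals the structure compensates exactly form its
**PPT** (preferential parallel train).  Learning is **heterosynaptic
STDP** on the input weights: a delay neuron firing later than its
neighbour is potentiated (Δw = *A*₊e^(−Δt/τ₊)), an earlier one depressed,
so repeated presentation synchronises the delay layer and the PPT
converges to the presented pattern.  Recognition tolerance is set by the
target's *L*<sub>d</sub> and by per-feature output weights.

The **trapezoid method** reproduces the target summation analytically:
each branch contributes a right trapezoid (plateau = `w_out[i]`, flank
slope = *L*<sub>d</sub>); the heights where the train's spikes intersect
the trapezoids (*target efficacies*) sum, per crossing step, to the
summation peaks *S*<sub>p</sub>, and the maximum peak decides firing.
It matches the event-driven engine to numerical precision whenever the
output weights guarantee the target turns active only at the last
arrival.

Multiclass systems assign one trained structure per class; among firing
targets the earliest spike wins, and an *enhanced* variant adds
redundancy modules plus inhibitory "muting" bundles that cancel
competitors' pending spikes.

## Worked example

```python
import numpy as np
from nmnsd import (NMNSDStructure, NeuronParams, ParallelSpikeTrain,
                   ppt, recognize)

p = NeuronParams.from_threshold(1.04, Ld=0.05)
s = NMNSDStructure(w_in=np.array([1.08, 1.10]),
                   w_out=np.array([0.6, 0.6]),
                   delay_params=p, target_params=p)
print(ppt(s))                                         # [-2.5]
r = recognize(s, ParallelSpikeTrain(np.array([0.0, 2.5])))
print(r.fired, r.Sp_M, r.ttf_T, r.t_spike)
```

prints

```
[-2.5]
True 1.2 5.0 17.5
```

The structure delays branch 1 by 12.5 ms and branch 2 by 10 ms, so its
preferred input interval is t₁ − t₂ = −2.5 ms.  The presented train has
exactly that lag: both contributions reach the target at 12.5 ms, the
summation peak is 0.6 + 0.6 = 1.2 ≥ 1.04, and the target fires 1/(1.2−1)
= 5 ms later, at 17.5 ms.  The same train shifted by +20 ms is rejected
(`Sp_M = 0.6`): the first contribution has fully decayed before the
second arrives.

The `examples/` directory has one short script per capability: LIFL
latency and the event engine, static recognition, trapezoid-chart
analysis and export, STDP template learning, an end-to-end synthetic
sweep, image latency encoding, the multichannel peak-time pipeline, and
an opt-in MNIST benchmark (`examples/mnist_benchmark.py`, which only
reads locally downloaded IDX files).

A thin CLI mirrors the library: `nmnsd gen | train | predict | sweep |
optimize-out | chart | simulate` (see `nmnsd --help`).

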