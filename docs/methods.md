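# Methods

This note records the model implemented by `nmnsd`, the numerical and
design choices made where the behaviour was genuinely open, what the
synthetic generators do and do not emulate, and the known limitations.

## Neuron model and engine

The LIFL neuron has two regimes around the threshold `S_th = 1 + d`:

- **passive** (`S < S_th`): linear decay `S(t+dt) = max(S0, S - Ld*dt)`.
  The floor at the resting value `S0` is part of the model — the state
  never undershoots rest.
- **active** (`S >= S_th`): the neuron is committed to fire after the
  latency `ttf = 1/(S - 1)`.  The supra-threshold growth law is
  implemented as `S' = 1 + (S-1)/(1 - (S-1)dt)`, the unique form for
  which evolving an active neuron by `dt` shortens its remaining latency
  by exactly `dt` (latency consistency).  That identity is the normative
  contract and is property-tested to 1e-12.

Pulses are Dirac deltas delivered over zero-delay connections.  The
engine is a discrete-event simulator with a priority queue keyed by
`(time, kind, source id, insertion order)`: scheduled spikes sort before
pulse deliveries at the same instant, so a pulse landing exactly at a
neuron's spike time finds it already reset.  Scheduled spikes are
invalidated lazily via a per-neuron generation counter; an inhibitory
pulse that drags an active neuron below threshold therefore cancels its
pending spike — the mechanism behind the muting bundles.  After firing,
a neuron resets to `S0`/passive with no refractory period (the model
leaves refractoriness unspecified; a plain reset keeps the at-rest
assumption self-consistent, since each pattern is presented to a
structure at rest).  Times are in milliseconds throughout; simultaneity
comparisons use an absolute tolerance of 1e-9 ms.

## Structure conventions

A parallel spike train carries one spike per branch; silent branches are
`NaN`.  Relative intervals follow `dt[i] = t[i] - t[i+1]`, the sign
under which the PPT formula
`ppt[i] = 1/(w_in[i+1]-1) - 1/(w_in[i]-1)` literally equals the
intervals that make all delay-layer outputs reach the target
simultaneously.

STDP neighbour lags use `dt_out = (own spike time) - (neighbour's)`:
positive lag (own branch late) potentiates, which shortens the latency
and pulls the output earlier.  This is the only sign assignment under
which repeated presentation synchronises the layer; it is verified by
the convergence tests.  First/last branches have a single neighbour;
silent branches emit no timing signal and receive no update.  During
learning, weights are clamped to `[S_th + 1e-6, 1 + 1/0.1]` — every
branch stays supra-threshold and no latency falls below 0.1 ms (the
model itself states no bounds; unbounded updates could silence a branch
irrecoverably, since a silent branch receives no further learning
signal).

Heterosynaptic weights default to 0 ("weak lateral contributions"):
their functional role — carrying the neighbour's timing — is realised
directly by the update rule.  If configured non-zero they are delivered
as ordinary pulses between adjacent delay neurons during learning only,
and the delay layer is then simulated event-driven instead of in closed
form.

## Convergence of fixed-amplitude STDP

The update amplitude does not vanish at the fixed point: for lag
`e -> 0+` the weight change jumps to `A_plus`, so near the PPT each
presentation moves the delay-layer lag by a finite step
(~`A * sum_i |dL/dw_i|`, about 1.5-3 ms at the recommended operating
point with `A = 0.01`).  The trajectory therefore approaches the PPT
and then orbits it rather than settling.  `train_structure` offers three
observable remedies, all based on the layer's own output timing (never
on ground truth):

- `stop_tol`: stop as soon as every neighbour lag of the current
  presentation is below a tolerance (ms).  On jitter-free input the
  trajectory passes well inside 0.5 ms within a handful of
  presentations.
- `keep_best`: return the weights whose presentation showed the smallest
  maximum lag.  Reliable only on low-jitter data, since the observed lag
  confounds weight error with trial jitter.
- `average`: return the tail average of the weight trajectory (last half
  by default).  This is standard stochastic-approximation averaging: it
  cancels both the orbit and the jitter-driven noise, and it is the
  default for ensemble training.  On jittered templates (sigma = 1 ms)
  it recovers intervals to a few tenths of a millisecond.

## Trapezoid method

All bookkeeping reduces to target-arrival times
`arr[i] = t[i] + 1/(A*w_in[i] - 1)`.  Triangle bases are `w_out/Ld`
(target decay); rectangle bases follow the crossing order (ascending
`arr`, ties to the lower branch index) with
`rect[ref_k] = max(0, rect[ref_k-1] + tri[ref_k-1] - gap)` where `gap`
is the inter-arrival interval at the target.  The clamp at zero encodes
full discharge: it activates exactly when the engine's target state
reached rest between two arrivals, and the shortfall is not propagated.
The chart's abscissae (`v_bar[0] = c`, then cumulative PPT intervals)
only matter for drawing; every computed quantity depends on differences,
so the anchor `c` is cosmetic.  On the reversed-time chart the train is
drawn at negated times sliding rightward — with that orientation the
offset of a spike past its trapezoid's left edge equals the arrival-time
difference, which is what the efficacy evaluation uses.

Analytic spike times use `ttf = 1/(Sp_M - 1)` and are exact when the
output weights satisfy the single-crossing guarantee (removing any one
weight drops the sum below threshold, so the target can only turn
active at the last arrival).  Outside that regime an arrival can land
during the target's active mode; no closed form is attempted — the
event-driven engine is the normative fallback and such results are
flagged `method="numeric"`.

Equivalence of the two routes (fire decision, maximum peak `Sp_M`,
spike time, each to 1e-9) is asserted over 1000 random instances with
2-8 branches drawn from the recommended parameter ranges
(`w_in` in [1.05, 1.15], `Ld` in [0.005, 0.15]).

## Encoders

Images: intensity-to-latency `t = (Imax - I)/Imax * t_range` with
`Imax = 255`, `t_range = 25` ms (an unwritten pixel fires last).
Square pixel fields are averaged (mean, not max/median) and ordered
row-major; the order matters because STDP couples adjacent branches, so
callers needing a different adjacency permute the image first.

Multichannel series: the per-channel latency feature is the time of the
absolute maximum within an analysis window (ties: earliest sample).
Channel selection ranks all channel pairs by ascending standard
deviation of the pairwise peak-time difference across trials, keeps
pairs with `|mean| >= 10` ms (default), and greedily covers channels
until the requested count; pairs duplicated across the two classes with
equal means are removed from both, as they carry no discriminative
power.  The greedy cover is this package's choice — how to turn ranked
pairs into a channel set is otherwise underdetermined.

## Classifiers

- Multiclass: one structure per class; the earliest firing target wins
  (an anticipated spike signals a better class fit); exact ties break to
  the first label; no firing target yields the explicit label
  `"indeterminate"`, which downstream accuracy counts as an error.
- Enhanced: `R` redundancy modules per class (input weights initialised
  uniformly in [1.05, 1.15] from per-module seeds), each feeding a final
  per-class target over a link of weight `S_th`, so any single module
  spike fires the final target.  Muting bundles connect final targets
  with inhibitory weight `-(S_th * R)`, enough to cancel any pending
  spike; the whole system runs as one event-driven network.
- Output-weight optimisation: Nelder-Mead over `w_out`, maximising
  validation accuracy with the weight-sum feasibility condition enforced
  by penalty and a small per-sample hinge margin (coefficient 1e-3)
  to smooth the otherwise piecewise-constant objective.  The result is
  kept only if it does not lose accuracy.
- Sweeps: full-factorial training cycles over `Ld` in [0.005, 0.08],
  `A` in [0.001, 0.04], `tau` in {5, 8} (defaults: 5 x 5 x 2 = 50
  cells); the best learner is the accuracy argmax, ties to the first
  cell in grid order.
- Layering: target spike times of several structures form a new train,
  affinely renormalised into [0, 25] ms so the next layer operates in
  its latency range; non-firing structures become silent branches.

## Synthetic data

Generators are pure functions of their seeds.  Spike-train classes are
interval templates with per-branch Gaussian jitter (template times drawn
in [0, 15] ms so implied latencies stay inside the 25 ms range; class
separation is enforced as an L-infinity distance between interval
vectors, >= 10 ms in the reference configuration, with jitter sigma =
1 ms).  Trials add a uniform random offset (exercising translation
invariance) and a fixed 6-sigma positivity margin so the jitter is never
truncated at t = 0.  Multichannel trials plant unit Gaussian bumps at
template latencies on disjoint informative channel blocks over white
noise; toy images are 7x7 binary strokes upscaled to 28x28 with
salt-and-pepper flips.

What passing tests show — and do not show: the generators realise
exactly the statistical structure the method assumes (stable relative
latencies, Gaussian perturbations, stationary classes).  Real recordings
add drifts, amplitude variation, correlated noise, missing spikes and
non-Gaussian artefacts; performance there depends on the upstream
feature extraction and is not certified by this suite.

## Problem sizes

The default test and acceptance configuration uses 2-8 branches for the
equivalence checks (1000 random instances), 4-branch two-class problems
with 25 training and 15 held-out trials per class for the end-to-end
sweep, and 10 training epochs per cell.  These sizes give stable
statistics for the properties being checked while keeping a full run in
the order of seconds on one core; all of them scale up linearly through
the same API.

## Known limitations

- One spike per branch per pattern; bursts are rejected by design.
- Consecutive patterns never interact: every recognition/learning call
  starts from rest (matching the model's at-rest assumption).
- Inhibition exists only as muting bundles between final targets; the
  delay layer itself is purely excitatory.
- Only linear sub-threshold decay is implemented.
- The trapezoid chart export is static (SVG/PNG/JSON); no interactive
  viewer is provided.
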