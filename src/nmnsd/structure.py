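"""The nMNSD structure: delay layer, target neuron, three weight sets.

An nMNSD of order ``n`` receives a *parallel spike train* — one spike per
input branch.  Each branch feeds a *delay neuron* ``D_i`` through an input
weight ``w_in[i]``; the delay neuron's spike latency ``1/(A*w_in[i] - 1)``
turns that weight into a controllable delay.  The delay-layer outputs
converge on a single *target neuron* through output weights ``w_out``; the
target fires when enough contributions arrive nearly simultaneously (the
*simultaneity condition*).  Heterosynaptic STDP between adjacent delay
neurons tunes the input weights online so that the layer's outputs
synchronise on the trains it is shown, making the structure a trainable
detector of a class of parallel spike trains.

The set of relative input intervals the structure compensates exactly is
its *preferential parallel train* (PPT); geometrically it is a 45-degree
line in the n-dimensional space of arrival times, through the point
``(1/(w_in[1]-1), ..., 1/(w_in[n]-1))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .lifl import (Connection, NeuronParams, SpikeEvent, run_events,
                   TIME_ATOL)

__all__ = [
    "ParallelSpikeTrain",
    "NMNSDStructure",
    "STDPParams",
    "DelayLayerResponse",
    "RecognitionResult",
    "delay_layer_outputs",
    "recognize",
    "ppt",
    "feature_point",
    "stdp_delta",
    "stdp_update",
    "train_structure",
    "TrainingLog",
]

# weight box used during learning: keeps every branch supra-threshold and
# its latency above a minimal value (0.1 ms)
_MIN_LATENCY_MS = 0.1
_W_EPS = 1e-6


@dataclass(frozen=True)
class ParallelSpikeTrain:
    """One spike per branch: ``n`` absolute spike times (ms) and amplitudes.

    A branch may be *silent* (no spike), encoded as ``NaN``; silent branches
    contribute nothing downstream.  Bursts (several spikes per branch) are
    not representable by design.
    """

    times: np.ndarray
    amplitudes: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("a parallel spike train needs >= 2 branches")
        finite = np.isfinite(t)
        if np.any(t[finite] < 0):
            raise ValueError("spike times must be >= 0")
        if np.any(np.isinf(t)):
            raise ValueError("spike times must be finite or NaN (silent)")
        a = self.amplitudes
        a = np.ones_like(t) if a is None else np.asarray(a, dtype=float)
        if a.shape != t.shape:
            raise ValueError("amplitudes must match the number of branches")
        object.__setattr__(self, "amplitudes", a)

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def silent(self) -> np.ndarray:
        """Boolean mask of silent (spike-less) branches."""
        return ~np.isfinite(self.times)

    def intervals(self) -> np.ndarray:
        """Relative intervals ``dt[i] = t[i] - t[i+1]`` of adjacent branches.

        The sign convention matches the PPT: a train lies on a structure's
        PPT exactly when its intervals equal :func:`ppt` of the structure.
        """
        return self.times[:-1] - self.times[1:]

    def shifted(self, delta: float) -> "ParallelSpikeTrain":
        return ParallelSpikeTrain(self.times + delta, self.amplitudes)


@dataclass
class STDPParams:
    """Heterosynaptic STDP parameters (potentiation/depression amplitudes
    and time constants).  Recommended: ``A_plus = -A_minus <= 0.01``,
    ``tau`` in 2-10 ms."""

    A_plus: float = 0.01
    A_minus: float = -0.01
    tau_plus: float = 5.0
    tau_minus: float = 5.0

    def __post_init__(self) -> None:
        if self.A_plus < 0 or self.A_minus > 0:
            raise ValueError("require A_plus >= 0 >= A_minus")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("time constants must be positive")


@dataclass
class NMNSDStructure:
    """Weights and neuron parameters of one nMNSD.

    ``w_in`` (input weights, the learned quantity), ``w_het``
    (heterosynaptic weights between adjacent delay neurons, ~0), ``w_out``
    (output weights, controlling per-feature relevance and tolerance).
    """

    w_in: np.ndarray
    w_out: np.ndarray
    w_het: np.ndarray | None = None
    delay_params: NeuronParams = field(default_factory=NeuronParams)
    target_params: NeuronParams = field(default_factory=NeuronParams)

    def __post_init__(self) -> None:
        self.w_in = np.asarray(self.w_in, dtype=float)
        self.w_out = np.asarray(self.w_out, dtype=float)
        n = self.w_in.size
        if n < 2:
            raise ValueError("an nMNSD needs at least 2 branches")
        if self.w_out.shape != (n,):
            raise ValueError("w_in and w_out must have one entry per branch")
        if self.w_het is None:
            self.w_het = np.zeros(n - 1)
        else:
            self.w_het = np.asarray(self.w_het, dtype=float)
            if self.w_het.shape != (n - 1,):
                raise ValueError("w_het needs one entry per adjacent pair")

    @property
    def n(self) -> int:
        return self.w_in.size

    @property
    def Sth(self) -> float:
        return self.target_params.Sth

    def copy(self) -> "NMNSDStructure":
        return NMNSDStructure(self.w_in.copy(), self.w_out.copy(),
                              self.w_het.copy(), self.delay_params,
                              self.target_params)

    @classmethod
    def default(cls, n: int, Ld: float = 0.05, Sth: float = 1.04,
                w_in: float = 1.08, w_out_sum: float = 1.2,
                ) -> "NMNSDStructure":
        """Structure at the recommended operating point: all neurons share
        ``S_th`` and ``Ld``, input weights start mid-range (latency
        ``ttf_max/2``), equal output weights summing to ``w_out_sum``."""
        p = NeuronParams.from_threshold(Sth, Ld=Ld)
        return cls(np.full(n, w_in), np.full(n, w_out_sum / n),
                   delay_params=p, target_params=p)


@dataclass
class DelayLayerResponse:
    """Delay-layer spike times ``t_out[i] = t_ES[i] + 1/(A*w_in[i]-1)``
    (NaN for silent branches) and the neighbour lags used by STDP."""

    t_out: np.ndarray

    @property
    def silent(self) -> np.ndarray:
        return ~np.isfinite(self.t_out)

    def neighbor_lag(self, i: int, j: int) -> float:
        """Signed lag ``dt_out = t_out[i] - t_out[j]`` (own minus neighbour);
        NaN if either branch is silent."""
        return float(self.t_out[i] - self.t_out[j])


@dataclass
class RecognitionResult:
    """Outcome of presenting a train to a structure.

    ``Sp`` are the target summation peaks (state right after each target
    arrival), ``Sp_M`` their maximum; the structure recognises the train
    (``fired``) iff ``Sp_M >= S_th``.  ``ttf_T`` is the target latency from
    the peak arrival to the emitted spike.  ``method`` is ``"engine"`` for
    event-driven results, ``"analytic"`` for trapezoid-method results,
    ``"numeric"`` when an analytic request fell back to the engine.
    """

    fired: bool
    Sp: np.ndarray
    Sp_M: float
    ttf_T: float | None = None
    t_spike: float | None = None
    method: str = "engine"


def delay_layer_outputs(s: NMNSDStructure, x: ParallelSpikeTrain,
                        include_het: bool = False) -> DelayLayerResponse:
    """Spike times of the delay layer for train ``x``.

    A branch fires iff its drive ``A_ES[i] * w_in[i]`` reaches the delay
    threshold; then ``t_out[i] = t_ES[i] + 1/(A*w_in[i] - 1)``.  Branches
    that stay sub-threshold (or carry no input spike) are silent (NaN).

    With ``include_het=True`` non-zero heterosynaptic weights are delivered
    as ordinary pulses between adjacent delay neurons (used during
    learning only) and the layer is simulated event-driven.
    """
    if s.n != x.n:
        raise ValueError(f"structure has {s.n} branches, train has {x.n}")
    drive = x.amplitudes * s.w_in
    if include_het and np.any(s.w_het != 0.0):
        return _delay_layer_engine(s, x, drive)
    t_out = np.full(s.n, math.nan)
    ok = ~x.silent & (drive >= s.delay_params.Sth)
    t_out[ok] = x.times[ok] + 1.0 / (drive[ok] - 1.0)
    return DelayLayerResponse(t_out=t_out)


def _delay_layer_engine(s: NMNSDStructure, x: ParallelSpikeTrain,
                        drive: np.ndarray) -> DelayLayerResponse:
    """Delay layer with lateral (heterosynaptic) pulses, simulated."""
    neurons = {i: s.delay_params for i in range(s.n)}
    conns = []
    for i in range(s.n - 1):
        w = float(s.w_het[i])
        if w != 0.0:
            conns.append(Connection(i, i + 1, w))
            conns.append(Connection(i + 1, i, w))
    evs = sorted(
        (SpikeEvent(t=float(x.times[i]), source=f"ES{i}", target=i,
                    contribution=float(drive[i]))
         for i in range(s.n) if not x.silent[i]),
        key=lambda e: e.t)
    res = run_events(evs, neurons, conns)
    t_out = np.full(s.n, math.nan)
    for nid, t in res.spikes:
        if math.isnan(t_out[nid]):  # first spike per branch
            t_out[nid] = t
    return DelayLayerResponse(t_out=t_out)


def recognize(s: NMNSDStructure, x: ParallelSpikeTrain) -> RecognitionResult:
    """Present ``x`` to the structure at rest (STDP off) and run the engine.

    Records the target summation peak after every target arrival; the train
    is recognised iff some peak reaches ``S_th``.  Arrivals during the
    target's active mode (the awkward closed-form case) are handled
    naturally by the event-driven evolution.
    """
    if s.n != x.n:
        raise ValueError(f"structure has {s.n} branches, train has {x.n}")
    drive = x.amplitudes * s.w_in
    neurons = {i: s.delay_params for i in range(s.n)}
    neurons["T"] = s.target_params
    conns = [Connection(i, "T", float(s.w_out[i])) for i in range(s.n)]
    evs = sorted(
        (SpikeEvent(t=float(x.times[i]), source=f"ES{i}", target=i,
                    contribution=float(drive[i]))
         for i in range(s.n) if not x.silent[i]),
        key=lambda e: e.t)
    res = run_events(evs, neurons, conns)

    t_spike = next((t for nid, t in res.spikes if nid == "T"), None)
    target_arrivals = [(t, S) for t, nid, S in res.arrivals if nid == "T"]
    if t_spike is not None:
        peaks = [(t, S) for t, S in target_arrivals
                 if t <= t_spike + TIME_ATOL]
    else:
        peaks = target_arrivals
    if not peaks:
        return RecognitionResult(fired=False, Sp=np.empty(0), Sp_M=0.0)
    Sp = np.array([S for _, S in peaks])
    k = int(np.argmax(Sp))
    Sp_M = float(Sp[k])
    fired = t_spike is not None
    ttf_T = (t_spike - peaks[k][0]) if fired else None
    return RecognitionResult(fired=fired, Sp=Sp, Sp_M=Sp_M,
                             ttf_T=ttf_T, t_spike=t_spike)


def ppt(s: NMNSDStructure) -> np.ndarray:
    """Preferential relative intervals of the structure.

    ``ppt[i] = 1/(w_in[i+1]-1) - 1/(w_in[i]-1)`` for adjacent branch pairs:
    the intervals ``t[i] - t[i+1]`` a train must carry (at unit amplitude)
    for all delay-layer outputs to reach the target simultaneously.
    """
    if np.any(s.w_in < s.delay_params.Sth):
        raise ValueError("PPT undefined: some branch is silent "
                         "(w_in below the delay threshold)")
    lat = 1.0 / (s.w_in - 1.0)
    return lat[1:] - lat[:-1]


def feature_point(s: NMNSDStructure) -> np.ndarray:
    """Anchor point of the PPT line in arrival-time feature space:
    ``(1/(w_in[1]-1), ..., 1/(w_in[n]-1))``.  The PPT line is this point
    plus multiples of the all-ones direction (slope 45 degrees)."""
    if np.any(s.w_in <= 1.0):
        raise ValueError("feature point undefined for w_in <= 1")
    return 1.0 / (s.w_in - 1.0)


def stdp_delta(dt_out: float, p: STDPParams) -> float:
    """Weight change evoked by a neighbour lag ``dt_out`` (own spike time
    minus the neighbour's).

    Positive lag (own neuron late) potentiates: ``A_plus*exp(-dt/tau_plus)``
    — a larger weight shortens the latency, pulling the output earlier.
    Negative lag depresses: ``A_minus*exp(dt/tau_minus)``.  Zero lag (or a
    silent neighbour, lag NaN) changes nothing: the PPT is a fixed point.
    """
    if math.isnan(dt_out) or dt_out == 0.0:
        return 0.0
    if dt_out > 0:
        return p.A_plus * math.exp(-dt_out / p.tau_plus)
    return p.A_minus * math.exp(dt_out / p.tau_minus)


def _weight_box(s: NMNSDStructure) -> tuple[float, float]:
    lo = s.delay_params.Sth + _W_EPS
    hi = 1.0 + 1.0 / _MIN_LATENCY_MS
    return lo, hi


def stdp_update(s: NMNSDStructure, x: ParallelSpikeTrain,
                p: STDPParams) -> NMNSDStructure:
    """One heterosynaptic-STDP step: returns the structure with input
    weights updated in response to the presented train.

    The delay-layer outputs are computed once on the pre-update weights;
    each branch then receives a contribution from each of its (at most two)
    neighbours.  First and last branches have a single neighbour; silent
    neighbours contribute nothing.  Weights are clamped to a box that keeps
    every branch supra-threshold with latency >= 0.1 ms.
    """
    resp = delay_layer_outputs(s, x, include_het=True)
    new_w = s.w_in.copy()
    for i in range(s.n):
        if resp.silent[i]:
            continue  # a silent branch emits no spike: no timing signal
        dw = 0.0
        for j in (i + 1, i - 1):
            if 0 <= j < s.n:
                dw += stdp_delta(resp.neighbor_lag(i, j), p)
        new_w[i] += dw
    lo, hi = _weight_box(s)
    np.clip(new_w, lo, hi, out=new_w)
    out = s.copy()
    out.w_in = new_w
    return out


@dataclass
class TrainingLog:
    """Per-presentation record of a training run."""

    weights: np.ndarray            # (presentations+1, n) input-weight history
    max_lag: np.ndarray            # (presentations,) max |neighbour lag| seen
    presentations: int
    converged: bool


def train_structure(s: NMNSDStructure,
                    dataset: Sequence[ParallelSpikeTrain],
                    p: STDPParams,
                    epochs: int = 1,
                    shuffle: bool = False,
                    seed: int | None = None,
                    stop_tol: float | None = None,
                    keep_best: bool = False,
                    average: bool | float = False,
                    ) -> tuple[NMNSDStructure, TrainingLog]:
    """Learning phase: apply :func:`stdp_update` per presented train.

    With fixed-amplitude STDP the weights do not settle pointwise — near
    the fixed point each presentation moves the delay-layer lag by a finite
    step, so the trajectory orbits the PPT (and jittered inputs add noise
    on top).  Three observable remedies are provided: ``stop_tol`` stops as
    soon as every neighbour lag of the current presentation is below the
    tolerance (ms); ``keep_best`` returns the weight vector whose
    presentation showed the smallest maximum lag; ``average`` returns the
    tail average of the weight trajectory (over the last half by default,
    or the last ``average`` fraction), which cancels both the orbit and
    the jitter response.  All three use only the layer's own output
    timing, never ground truth.
    """
    if not dataset:
        raise ValueError("training dataset is empty")
    n = s.n
    for x in dataset:
        if x.n != n:
            raise ValueError("all trains must match the structure order")
    rng = np.random.default_rng(seed)
    cur = s.copy()
    w_hist = [cur.w_in.copy()]
    lags: list[float] = []
    best_w, best_lag = cur.w_in.copy(), math.inf
    converged = False
    order = np.arange(len(dataset))
    for _ in range(epochs):
        if shuffle:
            rng.shuffle(order)
        for idx in order:
            x = dataset[idx]
            resp = delay_layer_outputs(cur, x, include_het=True)
            lag = _max_neighbor_lag(resp)
            lags.append(lag)
            if lag < best_lag:
                best_lag, best_w = lag, cur.w_in.copy()
            if stop_tol is not None and lag <= stop_tol:
                converged = True
                break
            cur = stdp_update(cur, x, p)
            w_hist.append(cur.w_in.copy())
        if converged:
            break
    if keep_best and best_lag < _max_neighbor_lag(
            delay_layer_outputs(cur, dataset[0], include_het=True)):
        cur = cur.copy()
        cur.w_in = best_w
    if average:
        frac = 0.5 if average is True else float(average)
        W = np.array(w_hist)
        tail = W[int(round(len(W) * (1.0 - frac))):]
        cur = cur.copy()
        cur.w_in = tail.mean(axis=0)
    log = TrainingLog(weights=np.array(w_hist), max_lag=np.array(lags),
                      presentations=len(lags), converged=converged)
    return cur, log


def _max_neighbor_lag(resp: DelayLayerResponse) -> float:
    """Largest |adjacent output lag| over firing pairs (inf if < 2 fire)."""
    t = resp.t_out[np.isfinite(resp.t_out)]
    if t.size < 2:
        return math.inf
    d = np.diff(resp.t_out)
    d = d[np.isfinite(d)]
    return float(np.max(np.abs(d))) if d.size else math.inf
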