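"""Leaky Integrate-and-Fire with Latency (LIFL) neurons and an event-driven engine.

The LIFL model extends the classical LIF with the *spike latency*
neurocomputational feature: once the internal state ``S`` crosses the firing
threshold ``S_th = 1 + d`` the neuron does not fire immediately but after a
state-dependent delay, the *time-to-fire*::

    ttf = 1 / (S - 1)

Below threshold (*passive mode*) the state decays linearly at rate ``Ld``
towards the resting value ``S0``; above threshold (*active mode*) the state
grows spontaneously so that the scheduled spike time is preserved:
evolving an active neuron for ``dt`` shortens its remaining latency by
exactly ``dt``.  Neurons exchange Dirac-delta pulses; a pulse of signed
amplitude ``w`` adds ``w`` to the post-synaptic state instantaneously.

This module is deliberately generic: it knows nothing about the nMNSD
topology, only about LIFL state evolution and time-ordered pulse delivery.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

__all__ = [
    "NeuronParams",
    "NeuronState",
    "SpikeEvent",
    "Connection",
    "passive_decay",
    "time_to_fire",
    "active_growth",
    "max_latency",
    "apply_input",
    "run_events",
    "EngineResult",
    "TIME_ATOL",
]

#: Absolute tolerance (ms) used when deciding whether two event times coincide.
TIME_ATOL = 1e-9


@dataclass(frozen=True)
class NeuronParams:
    """Static parameters of a LIFL neuron.

    Parameters
    ----------
    d : float
        Threshold constant (> 0); the firing threshold is ``S_th = 1 + d``
        and the maximum latency is ``ttf_max = 1/d``.
    Ld : float
        Linear sub-threshold decay rate (state units per ms, >= 0).
    S0 : float
        Resting state (default 0); passive decay never undershoots it.
    Smax : float
        Upper clamp on the state (default unbounded).
    """

    d: float = 0.04
    Ld: float = 0.05
    S0: float = 0.0
    Smax: float = math.inf

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError(f"threshold constant d must be > 0, got {self.d}")
        if self.Ld < 0:
            raise ValueError(f"decay parameter Ld must be >= 0, got {self.Ld}")
        if self.S0 > self.Sth:
            raise ValueError("resting state S0 must not exceed the threshold")

    @property
    def Sth(self) -> float:
        """Firing threshold ``1 + d``."""
        return 1.0 + self.d

    @classmethod
    def from_threshold(cls, Sth: float = 1.04, **kwargs) -> "NeuronParams":
        """Build parameters from a threshold value ``S_th`` (> 1)."""
        if Sth <= 1.0:
            raise ValueError(f"threshold must exceed 1, got {Sth}")
        return cls(d=Sth - 1.0, **kwargs)


@dataclass
class NeuronState:
    """Dynamic state of a LIFL neuron.

    ``mode`` is ``"active"`` iff ``S >= S_th`` at ``t_last``; in that case
    ``t_fire = t_last + 1/(S - 1)`` is the scheduled spike time.
    """

    S: float = 0.0
    mode: str = "passive"
    t_last: float = 0.0
    t_fire: float | None = None


@dataclass(frozen=True, order=True)
class SpikeEvent:
    """A Dirac-delta pulse delivered to ``target`` at time ``t``.

    ``contribution`` is the signed amplitude x weight added to the target
    state.  ``source`` identifies the emitting neuron or external branch.
    """

    t: float
    source: Hashable = field(compare=False, default=None)
    target: Hashable = field(compare=False, default=None)
    contribution: float = field(compare=False, default=0.0)

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"event time must be >= 0, got {self.t}")


@dataclass(frozen=True)
class Connection:
    """Zero-delay weighted link ``source -> target``."""

    source: Hashable
    target: Hashable
    weight: float


def passive_decay(S: float, dt: float, params: NeuronParams) -> float:
    """Linear sub-threshold decay over ``dt`` ms, floored at the resting state.

    Returns ``max(S0, S - Ld*dt)``.
    """
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    return max(params.S0, S - params.Ld * dt)


def time_to_fire(S: float, params: NeuronParams) -> float:
    """Spike latency ``ttf = 1/(S - 1)`` of an active neuron (``S >= S_th``)."""
    if S < params.Sth:
        raise ValueError(
            f"time_to_fire requires S >= Sth ({params.Sth}); got S={S}"
        )
    return 1.0 / (S - 1.0)


def active_growth(S: float, dt: float) -> float:
    """Supra-threshold spontaneous growth over ``dt`` ms.

    Defined by latency consistency: the returned state ``S'`` satisfies
    ``ttf(S') = ttf(S) - dt``, i.e. ``S' = 1 + (S - 1)/(1 - (S - 1) dt)``.
    ``dt`` must be strictly less than the current latency.
    """
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    x = S - 1.0
    if x * dt >= 1.0:
        raise ValueError(
            f"dt={dt} is not smaller than the remaining latency {1.0 / x}"
        )
    return 1.0 + x / (1.0 - x * dt)


def max_latency(params: NeuronParams) -> float:
    """Upper bound of the spike latency, ``ttf_max = 1/d``."""
    return 1.0 / params.d


def _advance(state: NeuronState, t: float, params: NeuronParams) -> NeuronState:
    """Evolve a state from ``state.t_last`` to ``t`` with no input."""
    dt = t - state.t_last
    if dt < 0:
        raise ValueError("cannot evolve a neuron backwards in time")
    if dt == 0:
        return state
    if state.mode == "active":
        S = active_growth(state.S, dt)
        return NeuronState(S=S, mode="active", t_last=t, t_fire=state.t_fire)
    return NeuronState(S=passive_decay(state.S, dt, params), mode="passive",
                       t_last=t, t_fire=None)


def apply_input(state: NeuronState, ev: SpikeEvent,
                params: NeuronParams) -> NeuronState:
    """Deliver a pulse: evolve to ``ev.t``, add the contribution, re-evaluate mode.

    The state is clamped to ``[S0, Smax]``.  If the neuron is (still or
    newly) active the spike is rescheduled at ``ev.t + ttf``; an inhibitory
    contribution that drags an active neuron below threshold cancels its
    pending spike.
    """
    if ev.t < state.t_last:
        raise ValueError("event precedes the neuron's last update")
    st = _advance(state, ev.t, params)
    S = st.S + ev.contribution
    S = min(max(S, params.S0), params.Smax)
    if S >= params.Sth:
        return NeuronState(S=S, mode="active", t_last=ev.t,
                           t_fire=ev.t + time_to_fire(S, params))
    return NeuronState(S=S, mode="passive", t_last=ev.t, t_fire=None)


@dataclass
class EngineResult:
    """Outcome of :func:`run_events`.

    ``spikes`` lists emitted ``(neuron id, time)`` pairs in order;
    ``arrivals`` records ``(t, target, S_after)`` for every delivered pulse
    (the post-arrival state is the *summation peak* used by the nMNSD
    recognition analysis).
    """

    spikes: list[tuple[Hashable, float]]
    arrivals: list[tuple[float, Hashable, float]]
    states: dict[Hashable, NeuronState]


# heap event kinds: fires sort before deliveries at equal times so that a
# pulse landing exactly at a scheduled spike time finds the neuron reset.
_FIRE, _DELIVER = 0, 1


def run_events(events: Iterable[SpikeEvent],
               neurons: dict[Hashable, NeuronParams],
               connections: Sequence[Connection] = (),
               t_stop: float | None = None) -> EngineResult:
    """Run the event-driven simulation until the queue drains (or ``t_stop``).

    External ``events`` must be sorted by time.  All connections are
    instantaneous: when a neuron's scheduled spike time is reached it emits
    a spike, resets to rest, and its efferent pulses are delivered at the
    same instant.  Simultaneous events are processed in a deterministic
    order (time, kind, source id, insertion order).
    """
    events = list(events)
    for a, b in zip(events, events[1:]):
        if b.t < a.t:
            raise ValueError("external events must be sorted by time")

    states: dict[Hashable, NeuronState] = {
        nid: NeuronState(S=p.S0) for nid, p in neurons.items()
    }
    efferents: dict[Hashable, list[Connection]] = {}
    for c in connections:
        if c.source not in neurons or c.target not in neurons:
            raise KeyError(f"connection {c} references an unknown neuron")
        efferents.setdefault(c.source, []).append(c)
    # generation counter invalidates stale scheduled-fire heap entries
    gen: dict[Hashable, int] = {nid: 0 for nid in neurons}

    heap: list[tuple] = []
    seq = 0
    for ev in events:
        if ev.target not in neurons:
            raise KeyError(f"event targets unknown neuron {ev.target!r}")
        heap.append((ev.t, _DELIVER, _key(ev.source), seq, ev))
        seq += 1
    heapq.heapify(heap)

    spikes: list[tuple[Hashable, float]] = []
    arrivals: list[tuple[float, Hashable, float]] = []

    def schedule(nid: Hashable) -> None:
        nonlocal seq
        st = states[nid]
        if st.mode == "active":
            heapq.heappush(heap, (st.t_fire, _FIRE, _key(nid), seq,
                                  (nid, gen[nid])))
            seq += 1

    while heap:
        t, kind, _, _, payload = heapq.heappop(heap)
        if t_stop is not None and t > t_stop:
            break
        if kind == _FIRE:
            nid, g = payload
            if gen[nid] != g or states[nid].mode != "active":
                continue  # stale: the neuron was perturbed since scheduling
            spikes.append((nid, t))
            states[nid] = NeuronState(S=neurons[nid].S0, mode="passive",
                                      t_last=t, t_fire=None)
            gen[nid] += 1
            for c in efferents.get(nid, ()):
                ev = SpikeEvent(t=t, source=nid, target=c.target,
                                contribution=c.weight)
                heapq.heappush(heap, (t, _DELIVER, _key(nid), seq, ev))
                seq += 1
        else:
            ev = payload
            nid = ev.target
            states[nid] = apply_input(states[nid], ev, neurons[nid])
            gen[nid] += 1
            arrivals.append((t, nid, states[nid].S))
            schedule(nid)

    return EngineResult(spikes=spikes, arrivals=arrivals, states=states)


def _key(x: Hashable):
    """Total order over heterogeneous source ids (None sorts first)."""
    return (0, "") if x is None else (1, str(x))
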