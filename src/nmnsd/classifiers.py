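"""nMNSD-based classifiers: one-vs-all, multiclass ensembles, redundancy
with inhibitory muting, output-weight optimisation, parameter sweeps and
layer composition.

A multiclass system assigns one trained nMNSD per class.  If several
targets fire on the same input, the earliest target spike wins — an
anticipated spike signals a better fit with the class.  The *enhanced*
variant adds per-class redundancy modules (randomly initialised, then
trained) feeding a final per-class target, plus "muting" inhibitory
bundles between final targets: the first final target to fire cancels the
pending (still-latent) spikes of its competitors.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .encoding import features_to_train
from .lifl import Connection, SpikeEvent, run_events
from .metrics import ConfusionCounts
from .structure import (NMNSDStructure, ParallelSpikeTrain, STDPParams,
                        RecognitionResult, recognize, train_structure)

__all__ = [
    "Ensemble",
    "SweepGrid",
    "OvAPrediction",
    "INDETERMINATE",
    "predict_ova",
    "predict_multiclass",
    "predict_enhanced",
    "optimize_output_weights",
    "sweep",
    "layer_outputs",
    "build_ensemble",
    "train_ensemble",
    "evaluate",
]

#: Sentinel label returned when no class target fires.
INDETERMINATE = "indeterminate"


@dataclass
class Ensemble:
    """One (or ``redundancy``) trained structures per class."""

    structures: dict[Hashable, list[NMNSDStructure]]
    class_labels: list[Hashable]
    redundancy: int = 1
    inhibition: bool = False

    def __post_init__(self) -> None:
        ns = {st.n for mods in self.structures.values() for st in mods}
        if len(ns) > 1:
            raise ValueError("all structures must share the branch count")
        for lab in self.class_labels:
            if len(self.structures[lab]) != self.redundancy:
                raise ValueError(f"class {lab!r}: expected "
                                 f"{self.redundancy} modules")


@dataclass(frozen=True)
class SweepGrid:
    """Full-factorial grid over the decay rate ``Ld``, the STDP amplitude
    ``A`` (used as ``A_plus = -A_minus``) and time constant ``tau``.

    Defaults cover the recommended search ranges: Ld in [0.005, 0.08],
    A in [0.001, 0.04], tau in [5, 8].
    """

    Ld_range: tuple[float, ...] = (0.005, 0.01, 0.02, 0.04, 0.08)
    A_range: tuple[float, ...] = (0.001, 0.005, 0.01, 0.02, 0.04)
    tau_range: tuple[float, ...] = (5.0, 8.0)

    def __post_init__(self) -> None:
        if not (self.Ld_range and self.A_range and self.tau_range):
            raise ValueError("sweep grid must be non-empty")

    def cells(self):
        return itertools.product(self.Ld_range, self.A_range,
                                 self.tau_range)


@dataclass
class OvAPrediction:
    positive: bool
    score: float          # maximum target summation peak S_p,M
    latency: float | None  # target time-to-fire when positive


def predict_ova(s: NMNSDStructure, x: ParallelSpikeTrain) -> OvAPrediction:
    """One-vs-all decision of a single trained structure: positive iff the
    target fires; the peak and latency are attached as confidence scores."""
    res = recognize(s, x)
    return OvAPrediction(positive=res.fired, score=res.Sp_M,
                         latency=res.ttf_T)


def predict_multiclass(e: Ensemble, x: ParallelSpikeTrain,
                       return_detail: bool = False):
    """Winner = the firing class with the earliest target spike.

    Exactly one firing class wins outright; several firing classes are
    resolved by the anticipated spike (exact time ties break to the first
    label in ``class_labels``); no firing class at all yields
    :data:`INDETERMINATE` — reported, never silently guessed.
    """
    results: dict[Hashable, RecognitionResult] = {}
    for lab in e.class_labels:
        # redundancy > 1 without inhibition: earliest module spike speaks
        best: RecognitionResult | None = None
        for st in e.structures[lab]:
            r = recognize(st, x)
            if r.fired and (best is None or not best.fired
                            or r.t_spike < best.t_spike):
                best = r
            elif best is None:
                best = r
        results[lab] = best
    firing = [(results[lab].t_spike, i, lab)
              for i, lab in enumerate(e.class_labels)
              if results[lab].fired]
    if not firing:
        label = INDETERMINATE
    else:
        label = min(firing)[2]
    return (label, results) if return_detail else label


def _mute_weight(e: Ensemble) -> float:
    """Inhibitory muting amplitude: minus the largest final-target drive,
    enough to cancel any pending spike."""
    sth = next(iter(e.structures.values()))[0].Sth
    return -(sth * e.redundancy)


def predict_enhanced(e: Ensemble, x: ParallelSpikeTrain):
    """Redundancy + muting-bundle decision, simulated as one network.

    Each class's redundancy modules feed a final per-class LIFL target;
    any single module spike drives the final target past threshold (each
    link carries weight ``S_th``).  With ``inhibition`` on, every final
    target sends a muting (inhibitory) pulse to the other final targets
    when it fires, cancelling spikes still in their latency period; the
    winner is the class whose final target actually spikes first.
    """
    if e.redundancy < 1:
        raise ValueError("redundancy must be >= 1")
    if not e.inhibition:
        return predict_multiclass(e, x)

    neurons: dict = {}
    conns: list[Connection] = []
    events: list[SpikeEvent] = []
    for lab in e.class_labels:
        final = ("final", lab)
        mods = e.structures[lab]
        neurons[final] = mods[0].target_params
        for m, st in enumerate(mods):
            tgt = ("T", lab, m)
            neurons[tgt] = st.target_params
            for i in range(st.n):
                nid = ("D", lab, m, i)
                neurons[nid] = st.delay_params
                conns.append(Connection(nid, tgt, float(st.w_out[i])))
                if not x.silent[i]:
                    events.append(SpikeEvent(
                        t=float(x.times[i]), source=f"ES{i}", target=nid,
                        contribution=float(x.amplitudes[i] * st.w_in[i])))
            conns.append(Connection(tgt, final, st.Sth))
    mute = _mute_weight(e)
    for lab_a in e.class_labels:
        for lab_b in e.class_labels:
            if lab_a != lab_b:
                conns.append(Connection(("final", lab_a),
                                        ("final", lab_b), mute))
    events.sort(key=lambda ev: ev.t)
    res = run_events(events, neurons, conns)
    for nid, _t in res.spikes:
        if isinstance(nid, tuple) and nid[0] == "final":
            return nid[1]
    return INDETERMINATE


def optimize_output_weights(s: NMNSDStructure,
                            validation: Sequence[tuple[ParallelSpikeTrain,
                                                       bool]],
                            enforce_case1: bool = False,
                            maxiter: int = 200,
                            ) -> NMNSDStructure:
    """Nelder-Mead (fminsearch-style) search over the output weights.

    Maximises one-vs-all validation accuracy with the feasibility
    conditions enforced by penalty: the weights must sum to at least
    ``S_th`` (and, optionally, keep the single-crossing guarantee).  A tiny
    hinge-margin term breaks plateaus of the piecewise-constant accuracy.
    The input weights stay frozen; the result is returned only if it does
    not lose accuracy, so optimisation never hurts.
    """
    if not validation:
        raise ValueError("validation set is empty")
    Sth = s.Sth

    def objective(w: np.ndarray) -> float:
        pen = 0.0
        if np.any(w < 0):
            pen += float(np.sum(np.maximum(0.0, -w))) * 100.0
        tot = float(np.sum(np.maximum(w, 0.0)))
        if tot < Sth:
            pen += (Sth - tot) * 100.0
        if enforce_case1:
            excess = tot - np.maximum(w, 0.0) - Sth
            pen += float(np.sum(np.maximum(0.0, excess))) * 100.0
        if pen:
            return pen + 1.0
        cand = s.copy()
        cand.w_out = np.asarray(w, dtype=float)
        correct, hinge = 0, 0.0
        for x, positive in validation:
            r = recognize(cand, x)
            if r.fired == positive:
                correct += 1
            # per-sample hinge margin smooths the accuracy plateaus
            hinge += max(0.0, (Sth - r.Sp_M) if positive
                         else (r.Sp_M - Sth) + 0.02)
        acc = correct / len(validation)
        return -acc + 1e-3 * hinge / len(validation)

    base = objective(s.w_out)
    res = minimize(objective, s.w_out, method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 1e-4,
                            "fatol": 1e-6})
    if res.fun < base - 1e-12 and objective(res.x) <= base:
        out = s.copy()
        out.w_out = np.asarray(res.x, dtype=float)
        return out
    return s


def build_ensemble(labels: Sequence[Hashable], n: int, *,
                   Ld: float = 0.05, Sth: float = 1.04,
                   w_out_sum: float = 1.2, redundancy: int = 1,
                   inhibition: bool = False,
                   seed: int | None = None) -> Ensemble:
    """Untrained ensemble; with ``redundancy > 1`` the modules' input
    weights are initialised uniformly in [1.05, 1.15] (per-module streams
    derived from ``seed``) to broaden their differentiation."""
    rng = np.random.default_rng(seed)
    structures: dict[Hashable, list[NMNSDStructure]] = {}
    for lab in labels:
        mods = []
        for _ in range(redundancy):
            st = NMNSDStructure.default(n, Ld=Ld, Sth=Sth,
                                        w_out_sum=w_out_sum)
            if redundancy > 1:
                st.w_in = rng.uniform(1.05, 1.15, size=n)
            mods.append(st)
        structures[lab] = mods
    return Ensemble(structures=structures, class_labels=list(labels),
                    redundancy=redundancy, inhibition=inhibition)


def train_ensemble(e: Ensemble,
                   dataset: Sequence[tuple[ParallelSpikeTrain, Hashable]],
                   p: STDPParams, epochs: int = 10, shuffle: bool = True,
                   seed: int | None = None, stop_tol: float | None = None,
                   average: bool | float = True) -> Ensemble:
    """Train every module on its own class's trains (separate learning)."""
    by_class: dict[Hashable, list[ParallelSpikeTrain]] = {
        lab: [] for lab in e.class_labels}
    for x, lab in dataset:
        by_class[lab].append(x)
    out: dict[Hashable, list[NMNSDStructure]] = {}
    ss = np.random.SeedSequence(seed)
    for lab in e.class_labels:
        if not by_class[lab]:
            raise ValueError(f"no training trains for class {lab!r}")
        mods = []
        for st, child in zip(e.structures[lab],
                             ss.spawn(len(e.structures[lab]))):
            trained, _ = train_structure(
                st, by_class[lab], p, epochs=epochs, shuffle=shuffle,
                seed=int(child.generate_state(1)[0] % (2**31)),
                stop_tol=stop_tol, average=average)
            mods.append(trained)
        out[lab] = mods
    return Ensemble(structures=out, class_labels=e.class_labels,
                    redundancy=e.redundancy, inhibition=e.inhibition)


def evaluate(e: Ensemble,
             dataset: Sequence[tuple[ParallelSpikeTrain, Hashable]],
             positive_label: Hashable | None = None,
             ) -> dict[str, float]:
    """Accuracy/precision/recall of the ensemble on labelled trains.

    Indeterminate predictions count as errors.  Precision/recall take
    ``positive_label`` (default: the first class) as the preferred class.
    """
    pos = positive_label if positive_label is not None else e.class_labels[0]
    tp = fp = tn = fn = 0
    correct = 0
    for x, lab in dataset:
        pred = predict_enhanced(e, x) if e.inhibition \
            else predict_multiclass(e, x)
        if pred == lab:  # indeterminate never equals a label: it is an error
            correct += 1
        if lab == pos:
            if pred == pos:
                tp += 1
            else:
                fn += 1
        else:
            if pred == pos:
                fp += 1
            else:
                tn += 1
    c = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    return {"accuracy": correct / len(dataset) if dataset else 0.0,
            "precision": c.precision, "recall": c.recall,
            "tp": tp, "fp": fp, "tn": tn, "fn": fn, "n": c.total}


def sweep(train_set: Sequence[tuple[ParallelSpikeTrain, Hashable]],
          val_set: Sequence[tuple[ParallelSpikeTrain, Hashable]],
          grid: SweepGrid = SweepGrid(), *, seed: int | None = None,
          Sth: float = 1.04, w_out_sum: float = 1.2, epochs: int = 10,
          stop_tol: float | None = None,
          ) -> tuple[pd.DataFrame, dict]:
    """Full-factorial training cycles over the parameter grid.

    For every ``(Ld, A, tau)`` cell a fresh ensemble (one structure per
    class) is trained on ``train_set`` and scored on ``val_set``.  Returns
    the per-cell metric table and the *best learner* cell (argmax accuracy,
    ties to the first cell in grid order).  Reproducible under ``seed``.
    """
    labels = sorted({lab for _, lab in train_set}, key=str)
    n = train_set[0][0].n
    rows = []
    best = None
    for Ld, A, tau in grid.cells():
        e = build_ensemble(labels, n, Ld=Ld, Sth=Sth, w_out_sum=w_out_sum)
        p = STDPParams(A_plus=A, A_minus=-A, tau_plus=tau, tau_minus=tau)
        e = train_ensemble(e, train_set, p, epochs=epochs, shuffle=True,
                           seed=seed, stop_tol=stop_tol)
        m = evaluate(e, val_set)
        row = {"Ld": Ld, "A": A, "tau": tau, **m}
        rows.append(row)
        if best is None or m["accuracy"] > best["accuracy"] + 1e-12:
            best = {**row, "ensemble": e}
    return pd.DataFrame(rows), best


def layer_outputs(structures: Sequence[NMNSDStructure],
                  x: ParallelSpikeTrain,
                  t_range: float = 25.0) -> ParallelSpikeTrain:
    """Compose a layer: the target spike times of several structures form a
    new parallel spike train, affinely renormalised into ``[0, t_range]``
    so the next layer operates within its latency range.

    Non-firing structures yield silent branches; if no structure fires the
    composition is undefined and an error is raised.  The renormalisation
    preserves the rank order of the spike times; identical spike times map
    to a zero-interval train at time 0.
    """
    spikes = np.full(len(structures), math.nan)
    for i, st in enumerate(structures):
        r = recognize(st, x)
        if r.fired:
            spikes[i] = r.t_spike
    firing = np.isfinite(spikes)
    if not firing.any():
        raise ValueError("no structure in the layer fired")
    lo, hi = float(np.nanmin(spikes)), float(np.nanmax(spikes))
    if hi == lo:
        out = np.where(firing, 0.0, math.nan)
        return ParallelSpikeTrain(times=out)
    scaled = features_to_train(np.nan_to_num(spikes, nan=lo), lo, hi,
                               t_range).times
    return ParallelSpikeTrain(times=np.where(firing, scaled, math.nan))
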