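"""The trapezoid method: analytical decomposition of the target summation.

Instead of simulating the structure, the target's multiple-input
single-output transfer function is decomposed into ``n`` right trapezoids
drawn at the *input* of the structure on a reversed-time axis.  The
trapezoid of branch ``i`` has height ``w_out[i]``; its triangle base
``tri = w_out[i]/Ld`` encodes the target's linear discharge, and its
rectangle base encodes how much of the previous contributions' plateau is
left when branch ``i``'s contribution lands.  The heights at which the
train's spikes intersect the trapezoids (*target efficacies*) sum, per
crossing step, to the target summation peaks — reproducing the event-driven
engine exactly whenever the target state never floors at rest between
arrivals (and the rectangle clamp handles exactly that case).

Internally all bookkeeping uses target-arrival times
``arr[i] = t_ES[i] + 1/(A*w_in[i] - 1)``; the chart abscissae exist for
drawing and JSON export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .structure import (NMNSDStructure, ParallelSpikeTrain,
                        RecognitionResult, ppt, recognize)

__all__ = [
    "Trapezoid",
    "TrapezoidChart",
    "CrossingOrder",
    "EfficacySet",
    "abscissae",
    "crossing_order",
    "build_chart",
    "efficacies",
    "peaks",
    "check_output_weights",
    "render_chart",
    "chart_to_json",
]


@dataclass(frozen=True)
class Trapezoid:
    """Per-branch trapezoid: left abscissa, rectangle and triangle bases
    (ms) and height ``w_out`` (state units)."""

    branch: int
    v_bar: float
    rect: float
    tri: float
    height: float


@dataclass(frozen=True)
class CrossingOrder:
    """Branch indices in the order their contributions reach the target."""

    refs: tuple[int, ...]

    def __post_init__(self) -> None:
        if sorted(self.refs) != list(range(len(self.refs))):
            raise ValueError("crossing order must be a permutation of 0..n-1")


@dataclass
class TrapezoidChart:
    """The full chart: trapezoids (in branch order), crossing order, the
    fictive anchor ``c`` and the target arrival times used to build it."""

    trapezoids: list[Trapezoid]
    crossing: CrossingOrder
    c: float
    arrivals: np.ndarray
    structure: NMNSDStructure
    train: ParallelSpikeTrain


@dataclass
class EfficacySet:
    """Matrix of target efficacies ``e[k, j]``: residual contribution of
    branch ``j`` at crossing step ``k`` (row order follows the crossing
    order)."""

    e: np.ndarray
    crossing: CrossingOrder


def _arrival_times(s: NMNSDStructure, x: ParallelSpikeTrain) -> np.ndarray:
    drive = x.amplitudes * s.w_in
    if np.any(x.silent) or np.any(drive < s.delay_params.Sth):
        raise ValueError("trapezoid method requires all branches to fire")
    return x.times + 1.0 / (drive - 1.0)


def abscissae(s: NMNSDStructure, c: float = 0.0) -> np.ndarray:
    """Left-side abscissae of the trapezoids on the reversed-time axis.

    ``v_bar[0] = c`` and each next abscissa adds the structure's
    preferential interval: ``v_bar[i] = c + sum_{k<i} ppt[k]``... with the
    PPT sign convention this equals ``c + (1/(w_in[i]-1) - 1/(w_in[0]-1))``.
    All downstream results depend on differences of ``v_bar`` only, so the
    anchor ``c`` is purely presentational.
    """
    intervals = ppt(s)  # raises on silent branches
    v = np.empty(s.n)
    v[0] = c
    v[1:] = c + np.cumsum(intervals)
    return v


def crossing_order(s: NMNSDStructure, x: ParallelSpikeTrain) -> CrossingOrder:
    """Ascending order of target-arrival times; ties break to the lower
    branch index (np.argsort stable sort)."""
    arr = _arrival_times(s, x)
    return CrossingOrder(refs=tuple(int(i) for i in
                                    np.argsort(arr, kind="stable")))


def build_chart(s: NMNSDStructure, x: ParallelSpikeTrain,
                c: float = 0.0) -> TrapezoidChart:
    """Build the trapezoid set for structure ``s`` crossed by train ``x``.

    Triangle bases are ``w_out/Ld`` (target decay).  Rectangle bases follow
    the crossing order: the first trapezoid is a bare triangle; each next
    rectangle is the previous trapezoid's remaining extent after the
    inter-arrival gap, clamped at zero when the target fully discharged
    between the two arrivals.
    """
    Ld = s.target_params.Ld
    if Ld <= 0:
        raise ValueError("trapezoid method requires target Ld > 0 "
                         "(finite triangle bases)")
    arr = _arrival_times(s, x)
    order = crossing_order(s, x)
    v = abscissae(s, c)
    tri = s.w_out / Ld
    rect = np.zeros(s.n)
    refs = order.refs
    for k in range(1, s.n):
        a, b = refs[k - 1], refs[k]
        gap = arr[b] - arr[a]
        rect[b] = max(0.0, rect[a] + tri[a] - gap)
    traps = [Trapezoid(branch=i, v_bar=float(v[i]), rect=float(rect[i]),
                       tri=float(tri[i]), height=float(s.w_out[i]))
             for i in range(s.n)]
    return TrapezoidChart(trapezoids=traps, crossing=order, c=c,
                          arrivals=arr, structure=s, train=x)


def _height_at(trap: Trapezoid, delta: float) -> float:
    """Height of the trapezoid's upper perimeter ``delta`` ms past its left
    side (negative delta: not yet arrived -> 0)."""
    if delta < 0:
        return 0.0
    if delta <= trap.rect:
        return trap.height
    return max(0.0, trap.height - (delta - trap.rect) *
               (trap.height / trap.tri))


def efficacies(chart: TrapezoidChart,
               x: ParallelSpikeTrain | None = None) -> EfficacySet:
    """Target efficacies at every crossing step.

    Step ``k`` rigidly places the train so that spike ``ref_k`` sits on its
    trapezoid's left side; branch ``j``'s efficacy is the height of its
    trapezoid's perimeter at ``j``'s position, which works out to the
    offset ``arr[ref_k] - arr[j]`` past the left edge.  The crossing
    branch itself sits at offset 0 and scores its full output weight.
    """
    if x is not None and x is not chart.train \
            and not np.array_equal(x.times, chart.train.times):
        raise ValueError("chart was built for a different train")
    arr = chart.arrivals
    refs = chart.crossing.refs
    n = arr.size
    e = np.zeros((n, n))
    for k, rk in enumerate(refs):
        for j in range(n):
            e[k, j] = _height_at(chart.trapezoids[j], arr[rk] - arr[j])
    return EfficacySet(e=e, crossing=chart.crossing)


def check_output_weights(s: NMNSDStructure) -> dict[str, bool]:
    """Static output-weight conditions.

    ``sum_ok``: the weights can drive the target past threshold at perfect
    simultaneity (``sum(w_out) >= S_th``).  ``case1_ok``: removing any one
    weight drops the sum below threshold, so the target can only turn
    active at the last arrival — the closed-form latency case.
    """
    tot = float(np.sum(s.w_out))
    Sth = s.Sth
    return {
        "sum_ok": tot >= Sth,
        "case1_ok": bool(np.all(tot - s.w_out < Sth)),
    }


def peaks(chart: TrapezoidChart,
          x: ParallelSpikeTrain | None = None) -> RecognitionResult:
    """Analytical recognition: summation peaks, fire decision and latency.

    ``Sp[k]`` is the row sum of the efficacy matrix; the train is
    recognised iff ``max Sp >= S_th``.  When the output weights satisfy the
    single-crossing guarantee (``case1_ok``) the spike time follows the
    closed-form latency ``1/(Sp_M - 1)`` from the peak arrival; otherwise
    an arrival could land during the target's active mode, the event-driven
    engine is the normative fallback and the result is flagged
    ``method="numeric"``.
    """
    eff = efficacies(chart, x)
    Sp = eff.e.sum(axis=1)
    k = int(np.argmax(Sp))
    Sp_M = float(Sp[k])
    Sth = chart.structure.Sth
    fired = Sp_M >= Sth
    if fired and not check_output_weights(chart.structure)["case1_ok"]:
        res = recognize(chart.structure, chart.train)
        return RecognitionResult(fired=res.fired, Sp=Sp, Sp_M=res.Sp_M,
                                 ttf_T=res.ttf_T, t_spike=res.t_spike,
                                 method="numeric")
    if not fired:
        return RecognitionResult(fired=False, Sp=Sp, Sp_M=Sp_M,
                                 method="analytic")
    ttf_T = 1.0 / (Sp_M - 1.0)
    t_peak = float(chart.arrivals[chart.crossing.refs[k]])
    return RecognitionResult(fired=True, Sp=Sp, Sp_M=Sp_M, ttf_T=ttf_T,
                             t_spike=t_peak + ttf_T, method="analytic")


def chart_to_json(chart: TrapezoidChart, path=None) -> str:
    """Export the chart geometry (+ efficacies) as JSON for external
    plotting; returns the JSON text and optionally writes it to ``path``."""
    eff = efficacies(chart)
    doc = {
        "c": chart.c,
        "crossing_order": [i + 1 for i in chart.crossing.refs],  # 1-based
        "arrival_times_ms": chart.arrivals.tolist(),
        "trapezoids": [
            {"branch": t.branch + 1, "v_bar": t.v_bar, "rect": t.rect,
             "tri": t.tri, "height": t.height}
            for t in chart.trapezoids
        ],
        "efficacies": eff.e.tolist(),
        "peaks": eff.e.sum(axis=1).tolist(),
    }
    text = json.dumps(doc, indent=2, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def render_chart(chart: TrapezoidChart, x: ParallelSpikeTrain | None = None,
                 out_path=None, ax=None):
    """Draw the chart: reversed-time axis, trapezoids, the train's spikes
    and the efficacy intersections at the maximal crossing step.

    Writes SVG/PNG when ``out_path`` is given (format from the suffix);
    returns the matplotlib Axes.
    """
    import matplotlib
    if out_path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.2))
    eff = efficacies(chart)
    Sp = eff.e.sum(axis=1)
    kmax = int(np.argmax(Sp))
    rk = chart.crossing.refs[kmax]
    arr = chart.arrivals
    cmap = plt.get_cmap("tab10")
    # chart coordinate of branch j at the maximal step: the crossing branch
    # sits on its own left side, others are offset by the arrival gap
    for j, trap in enumerate(chart.trapezoids):
        color = cmap(j % 10)
        xs = [trap.v_bar, trap.v_bar - trap.rect,
              trap.v_bar - trap.rect - trap.tri]
        ax.plot([xs[0], xs[0]], [0, trap.height], color=color, lw=1.5)
        ax.plot([xs[0], xs[1]], [trap.height, trap.height], color=color,
                lw=1.5)
        ax.plot([xs[1], xs[2]], [trap.height, 0], color=color, lw=1.5,
                label=f"branch {j + 1}")
        pos = trap.v_bar - (arr[rk] - arr[j])
        ax.axvline(pos, color=color, ls=":", lw=0.8)
        ax.plot([pos], [eff.e[kmax, j]], "o", color=color, ms=5)
    ax.set_xlabel("reversed time at the structure input (ms)")
    ax.set_ylabel("target efficacy (state units)")
    ax.invert_xaxis()
    ax.legend(fontsize=7, loc="upper right")
    ax.set_title(f"crossing order {[i + 1 for i in chart.crossing.refs]}, "
                 f"S_p,M = {Sp[kmax]:.3f}")
    if out_path is not None:
        ax.figure.savefig(out_path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
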