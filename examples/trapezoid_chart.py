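"""The trapezoid method: analyse a recognition without simulating it.

Each branch contributes a trapezoid (plateau = output weight, flank slope
= target decay Ld); the heights where the train's spikes intersect the
trapezoids are the target efficacies, and their per-crossing-step sums are
the summation peaks.  The analytic result matches the event-driven engine
exactly under the single-crossing output-weight condition.
"""

import numpy as np

from nmnsd import (NMNSDStructure, NeuronParams, ParallelSpikeTrain,
                   build_chart, check_output_weights, efficacies, peaks,
                   recognize, render_chart)

p = NeuronParams.from_threshold(1.04, Ld=0.05)
s = NMNSDStructure(w_in=np.array([1.07, 1.11, 1.06, 1.09]),
                   w_out=np.array([0.30, 0.30, 0.25, 0.30]),
                   delay_params=p, target_params=p)
# times near the PPT: per-branch delays are (14.3, 9.1, 16.7, 11.1) ms,
# so these inputs reach the target within ~1 ms of each other
lat = 1.0 / (s.w_in - 1.0)
t = 20.0 - lat + np.array([0.0, 0.5, -0.5, 0.3])
x = ParallelSpikeTrain(t - t.min())
print("output-weight conditions:", check_output_weights(s))

chart = build_chart(s, x)
print("crossing order (1-based):",
      [i + 1 for i in chart.crossing.refs])
for t in chart.trapezoids:
    print(f"  branch {t.branch + 1}: rect={t.rect:6.2f} ms  "
          f"tri={t.tri:5.1f} ms  height={t.height:.2f}")

pk = peaks(chart)
e = efficacies(chart).e
print("efficacies at the final crossing step:", np.round(e[-1], 3))
print("summation peaks per step:", np.round(pk.Sp, 3))
print(f"analytic:  fired={pk.fired}  S_p,M={pk.Sp_M:.3f}  "
      f"t_spike={pk.t_spike}")
r = recognize(s, x)
print(f"engine  :  fired={r.fired}  S_p,M={r.Sp_M:.3f}  "
      f"t_spike={r.t_spike}")

render_chart(chart, out_path="trapezoid_chart.svg")
print("wrote trapezoid_chart.svg (reversed-time chart with efficacy dots)")
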