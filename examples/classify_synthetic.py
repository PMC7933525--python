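"""End-to-end classification of two jittered spike-train classes.

Two random templates (interval separation >= 10 ms) are jittered with
sigma = 1 ms; a full-factorial sweep over the decay rate Ld and the STDP
parameters (A, tau) trains one structure per class in every cell and
scores it on held-out trials.  The best learner's accuracy is reported.
"""

from nmnsd import SweepGrid, sweep
from nmnsd.synth import gen_templates, gen_trials

templates = gen_templates(n_features=4, n_classes=2, min_separation=10.0,
                          seed=2024, jitter_sd=1.0)
train, val = [], []
for k, tpl in enumerate(templates):
    trials = gen_trials(tpl, 40, seed=5000 + k)
    train += [(x, tpl.label) for x in trials[:25]]
    val += [(x, tpl.label) for x in trials[25:]]
print(f"{len(train)} training / {len(val)} held-out trials, "
      f"{templates[0].n} branches")

grid = SweepGrid()  # Ld in [0.005, 0.08], A in [0.001, 0.04], tau in {5, 8}
table, best = sweep(train, val, grid, seed=99)
print(table[["Ld", "A", "tau", "accuracy", "precision", "recall"]]
      .sort_values("accuracy", ascending=False).head(5)
      .to_string(index=False))
print(f"\nbest learner: Ld={best['Ld']}, A={best['A']}, tau={best['tau']}"
      f" -> held-out accuracy {best['accuracy']:.3f}")
print("Small Ld is tolerant to jitter but unselective; large Ld rejects "
      "everything.  The sweep finds the trade-off automatically.")
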