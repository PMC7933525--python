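"""Ensembles: OvA/multiclass decisions, muting, optimisation, sweeps."""

import numpy as np
import pytest

from nmnsd import (Ensemble, INDETERMINATE, NMNSDStructure, ParallelSpikeTrain,
                   STDPParams, SweepGrid, build_ensemble, evaluate,
                   layer_outputs, optimize_output_weights, ppt,
                   predict_enhanced, predict_multiclass, predict_ova,
                   recognize, sweep, train_ensemble)
from nmnsd.synth import ClassTemplate, gen_templates, gen_trials

from conftest import make_structure, train_of


def structure_for_template(tpl, Ld=0.02, w_out_each=0.6):
    """Structure whose PPT equals the template intervals exactly."""
    lat = 15.0 - (tpl.times - tpl.times.mean())
    w_in = 1.0 + 1.0 / lat
    return make_structure(w_in, [w_out_each] * tpl.n, Ld=Ld)


def on_ppt_train(s, anchor=40.0):
    lat = 1.0 / (s.w_in - 1.0)
    t = anchor - lat
    return ParallelSpikeTrain(t - t.min())


class TestPredictOvA:
    def test_on_template_positive_with_full_peak(self):
        s = make_structure([1.06, 1.09, 1.12], [0.4, 0.4, 0.4])
        pred = predict_ova(s, on_ppt_train(s))
        assert pred.positive
        assert pred.score == pytest.approx(1.2)

    def test_far_off_template_negative(self, two_branch):
        pred = predict_ova(two_branch, train_of(0.0, 20.0))
        assert not pred.positive

    def test_global_shift_invariance(self, two_branch):
        a = predict_ova(two_branch, train_of(0.0, 2.5))
        b = predict_ova(two_branch, train_of(60.0, 62.5))
        assert a.positive == b.positive
        assert a.score == pytest.approx(b.score, abs=1e-9)


def two_class_ensemble(Ld=0.05, w_out_each=0.6):
    ta = ClassTemplate(intervals=(8.0,), label="A")
    tb = ClassTemplate(intervals=(-8.0,), label="B")
    sa = structure_for_template(ta, Ld=Ld, w_out_each=w_out_each)
    sb = structure_for_template(tb, Ld=Ld, w_out_each=w_out_each)
    e = Ensemble(structures={"A": [sa], "B": [sb]},
                 class_labels=["A", "B"])
    return e, ta, tb


class TestPredictMulticlass:
    def test_on_template_input_maps_to_its_class(self):
        e, ta, tb = two_class_ensemble()
        xa = on_ppt_train(e.structures["A"][0])
        xb = on_ppt_train(e.structures["B"][0])
        assert predict_multiclass(e, xa) == "A"
        assert predict_multiclass(e, xb) == "B"

    def test_earliest_spike_breaks_double_fire(self):
        # tolerant structures: both fire, the better fit spikes earlier
        e, *_ = two_class_ensemble(Ld=0.005)
        xa = on_ppt_train(e.structures["A"][0])
        label, detail = predict_multiclass(e, xa, return_detail=True)
        assert detail["A"].fired and detail["B"].fired
        assert detail["A"].t_spike < detail["B"].t_spike
        assert label == "A"

    def test_far_input_is_indeterminate(self):
        e, *_ = two_class_ensemble(Ld=0.08)
        assert predict_multiclass(e, train_of(0.0, 24.0)) == INDETERMINATE


class TestPredictEnhanced:
    def test_without_inhibition_equals_multiclass(self):
        e, *_ = two_class_ensemble()
        x = on_ppt_train(e.structures["A"][0])
        assert predict_enhanced(e, x) == predict_multiclass(e, x)

    def test_muting_cancels_later_final_target(self):
        e, *_ = two_class_ensemble(Ld=0.005)  # both classes would fire
        e.inhibition = True
        xa = on_ppt_train(e.structures["A"][0])
        assert predict_enhanced(e, xa) == "A"

    def test_single_class_firing_unchanged(self):
        e, *_ = two_class_ensemble(Ld=0.08)  # selective: one class fires
        x = on_ppt_train(e.structures["B"][0])
        assert predict_multiclass(e, x) == "B"
        e.inhibition = True
        assert predict_enhanced(e, x) == "B"

    def test_redundant_modules_with_inhibition(self):
        ta = ClassTemplate(intervals=(8.0,), label="A")
        tb = ClassTemplate(intervals=(-8.0,), label="B")
        mods = {lab: [structure_for_template(t, Ld=0.02) for _ in range(3)]
                for lab, t in (("A", ta), ("B", tb))}
        e = Ensemble(structures=mods, class_labels=["A", "B"],
                     redundancy=3, inhibition=True)
        xa = on_ppt_train(mods["A"][0])
        assert predict_enhanced(e, xa) == "A"


class TestOptimizeOutputWeights:
    def _validation(self, s, rng, n=20, spread=6.0):
        val = []
        for _ in range(n):
            x = on_ppt_train(s, anchor=rng.uniform(30, 50))
            val.append((x, True))
            bad = x.times + rng.uniform(spread, 2 * spread, size=s.n) \
                * rng.choice([-1.0, 1.0], size=s.n)
            val.append((ParallelSpikeTrain(np.maximum(bad, 0.0)), False))
        return val

    def test_optimal_weights_stay_put(self):
        s = make_structure([1.06, 1.10], [0.6, 0.6], Ld=0.05)
        val = self._validation(s, np.random.default_rng(0))
        out = optimize_output_weights(s, val)
        base = sum(recognize(s, x).fired == y for x, y in val)
        after = sum(recognize(out, x).fired == y for x, y in val)
        assert after >= base

    def test_noise_feature_weight_is_reduced(self):
        """A branch whose timing is pure noise ends up with relatively
        less output weight than the informative branches."""
        rng = np.random.default_rng(3)
        s = make_structure([1.06, 1.10, 1.08], [0.4, 0.4, 0.4], Ld=0.05)
        val = []
        for _ in range(25):
            x = on_ppt_train(s, anchor=rng.uniform(30, 50))
            t = x.times.copy()
            t[2] = rng.uniform(0.0, 25.0)  # branch 3 carries no signal
            val.append((ParallelSpikeTrain(t), True))
            bad = t.copy()
            bad[:2] += rng.uniform(6, 12, size=2) * rng.choice([-1, 1],
                                                               size=2)
            val.append((ParallelSpikeTrain(np.maximum(bad, 0.0)), False))
        out = optimize_output_weights(s, val, maxiter=300)
        rel = out.w_out / out.w_out.sum()
        assert rel[2] < rel[0] and rel[2] < rel[1]

    def test_accuracy_never_decreases(self):
        s = make_structure([1.06, 1.10], [0.55, 0.55], Ld=0.08)
        val = self._validation(s, np.random.default_rng(1), spread=4.0)
        base = sum(recognize(s, x).fired == y for x, y in val)
        out = optimize_output_weights(s, val)
        after = sum(recognize(out, x).fired == y for x, y in val)
        assert after >= base


class TestSweep:
    @staticmethod
    def _datasets(seed=11, n_train=20, n_val=15):
        tpls = gen_templates(4, 2, min_separation=10.0, seed=seed,
                             jitter_sd=1.0)
        train, val = [], []
        for k, tpl in enumerate(tpls):
            tr = gen_trials(tpl, n_train + n_val, seed=100 * seed + k)
            train += [(x, tpl.label) for x in tr[:n_train]]
            val += [(x, tpl.label) for x in tr[n_train:]]
        return train, val

    def test_single_cell_equals_single_run(self):
        train, val = self._datasets()
        grid = SweepGrid(Ld_range=(0.02,), A_range=(0.01,),
                         tau_range=(5.0,))
        table, best = sweep(train, val, grid, seed=2)
        assert len(table) == 1
        e = build_ensemble(sorted({l for _, l in train}, key=str),
                           train[0][0].n, Ld=0.02)
        p = STDPParams(A_plus=0.01, A_minus=-0.01, tau_plus=5, tau_minus=5)
        e = train_ensemble(e, train, p, epochs=10, shuffle=True, seed=2)
        m = evaluate(e, val)
        assert table.iloc[0]["accuracy"] == pytest.approx(m["accuracy"])

    def test_metrics_match_confusion_counts(self):
        train, val = self._datasets(seed=21)
        grid = SweepGrid(Ld_range=(0.02,), A_range=(0.01,),
                         tau_range=(5.0,))
        table, _ = sweep(train, val, grid, seed=4)
        row = table.iloc[0]
        n = row["tp"] + row["fp"] + row["tn"] + row["fn"]
        assert n == len(val)
        if row["tp"] + row["fp"]:
            assert row["precision"] == pytest.approx(
                row["tp"] / (row["tp"] + row["fp"]))
        if row["tp"] + row["fn"]:
            assert row["recall"] == pytest.approx(
                row["tp"] / (row["tp"] + row["fn"]))

    def test_separable_classes_reach_high_accuracy(self):
        train, val = self._datasets(seed=31, n_train=25, n_val=15)
        grid = SweepGrid(Ld_range=(0.01, 0.02, 0.04), A_range=(0.005, 0.01),
                         tau_range=(5.0,))
        table, best = sweep(train, val, grid, seed=5)
        assert best["accuracy"] >= 0.95


class TestLayerOutputs:
    def test_spike_times_form_normalised_train(self):
        e, *_ = two_class_ensemble(Ld=0.005)
        structures = [e.structures["A"][0], e.structures["B"][0]]
        x = on_ppt_train(structures[0])
        out = layer_outputs(structures, x)
        assert out.n == 2
        assert out.times.min() == pytest.approx(0.0)
        assert out.times.max() == pytest.approx(25.0)
        # structure A fires earlier on its own template
        assert out.times[0] < out.times[1]

    def test_identical_spikes_collapse_to_zero_interval(self):
        s = make_structure([1.06, 1.10], [0.6, 0.6])
        out = layer_outputs([s, s], on_ppt_train(s))
        assert out.times == pytest.approx([0.0, 0.0])

    def test_rank_order_preserved(self):
        e, *_ = two_class_ensemble(Ld=0.005)
        structures = [e.structures["B"][0], e.structures["A"][0]]
        x = on_ppt_train(e.structures["A"][0])
        out = layer_outputs(structures, x)
        assert out.times[1] < out.times[0]

    def test_no_fire_raises(self):
        s = make_structure([1.08, 1.08], [0.6, 0.6], Ld=0.08)
        with pytest.raises(ValueError):
            layer_outputs([s], train_of(0.0, 20.0))
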