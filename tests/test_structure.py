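"""nMNSD statics (recognition, PPT) and dynamics (heterosynaptic STDP)."""

import math

import numpy as np
import pytest

from nmnsd import (NMNSDStructure, ParallelSpikeTrain, STDPParams,
                   delay_layer_outputs, feature_point, ppt, recognize,
                   stdp_delta, stdp_update, train_structure)
from nmnsd.synth import ClassTemplate, gen_trials

from conftest import make_structure, train_of


class TestDelayLayer:
    def test_per_branch_latencies(self):
        s = make_structure([1.08, 1.10], [0.6, 0.6])
        resp = delay_layer_outputs(s, train_of(0.0, 0.0))
        assert resp.t_out == pytest.approx([12.5, 10.0])

    def test_equal_weights_shift_equally(self):
        s = make_structure([1.08, 1.08], [0.6, 0.6])
        resp = delay_layer_outputs(s, train_of(0.0, 2.5))
        assert resp.t_out == pytest.approx([12.5, 15.0])
        assert resp.neighbor_lag(1, 0) == pytest.approx(2.5)

    def test_subthreshold_branch_is_silent(self):
        s = make_structure([1.00, 1.08], [0.6, 0.6])
        resp = delay_layer_outputs(s, train_of(0.0, 0.0))
        assert resp.silent[0] and not resp.silent[1]
        assert resp.t_out[1] == pytest.approx(12.5)

    def test_branch_count_mismatch(self):
        s = make_structure([1.08, 1.08], [0.6, 0.6])
        with pytest.raises(ValueError):
            delay_layer_outputs(s, train_of(0.0, 1.0, 2.0))


class TestRecognize:
    def test_compensated_lag_fires(self, two_branch):
        r = recognize(two_branch, train_of(0.0, 2.5))
        assert r.fired
        assert r.Sp_M == pytest.approx(1.2)
        assert r.ttf_T == pytest.approx(5.0)
        assert r.t_spike == pytest.approx(17.5)

    def test_decayed_first_contribution_blocks(self, two_branch):
        r = recognize(two_branch, train_of(0.0, 20.0))
        assert not r.fired
        assert r.Sp_M == pytest.approx(0.6)

    def test_translation_invariance(self, two_branch):
        r = recognize(two_branch, train_of(100.0, 102.5))
        assert r.fired and r.t_spike == pytest.approx(117.5)

    def test_silent_branch_can_still_recognize(self):
        # remaining output weights sum past threshold
        s = make_structure([1.0, 1.08, 1.08], [0.4, 0.6, 0.6])
        r = recognize(s, train_of(0.0, 0.0, 0.0))
        assert r.fired and r.Sp_M == pytest.approx(1.2)


class TestPPT:
    def test_symmetric_weights_zero_interval(self):
        s = make_structure([1.08, 1.08], [0.6, 0.6])
        assert ppt(s) == pytest.approx([0.0])

    @pytest.mark.parametrize("w_in, expected", [
        ([1.05, 1.10], [-10.0]),
        ([1.10, 1.05], [+10.0]),
    ])
    def test_antisymmetry(self, w_in, expected):
        s = make_structure(w_in, [0.6, 0.6])
        assert ppt(s) == pytest.approx(expected)

    def test_silent_branch_rejected(self):
        s = make_structure([1.00, 1.08], [0.6, 0.6])
        with pytest.raises(ValueError):
            ppt(s)

    def test_on_ppt_train_is_simultaneous_and_maximal(self):
        """A train whose intervals equal the PPT arrives synchronously and
        peaks at the full output-weight sum."""
        s = make_structure([1.06, 1.09, 1.12], [0.4, 0.4, 0.4])
        lat = 1.0 / (s.w_in - 1.0)
        times = 50.0 - lat  # equal arrival at t = 50
        x = ParallelSpikeTrain(times - times.min())
        assert x.intervals() == pytest.approx(ppt(s), abs=1e-12)
        resp = delay_layer_outputs(s, x)
        assert np.ptp(resp.t_out) < 1e-9
        r = recognize(s, x)
        assert r.Sp_M == pytest.approx(float(np.sum(s.w_out)))


class TestFeaturePoint:
    def test_coordinates(self):
        s = make_structure([1.08, 1.10], [0.6, 0.6])
        assert feature_point(s) == pytest.approx([12.5, 10.0])

    def test_equal_weights(self):
        s = make_structure([1.08] * 3, [0.4] * 3)
        assert feature_point(s) == pytest.approx([12.5] * 3)

    def test_latency_range_extremes(self):
        s = make_structure([1.04, 2.0], [0.6, 0.6])
        assert feature_point(s) == pytest.approx([25.0, 1.0])

    def test_rejects_subunit_weight(self):
        s = make_structure([1.08, 1.08], [0.6, 0.6])
        s.w_in = np.array([0.9, 1.08])
        with pytest.raises(ValueError):
            feature_point(s)


class TestSTDPDelta:
    def test_zero_lag_is_fixed(self):
        assert stdp_delta(0.0, STDPParams()) == 0.0

    @pytest.mark.parametrize("dt, expected", [
        (+5.0, 0.01 * math.exp(-1.0)),
        (-5.0, -0.01 * math.exp(-1.0)),
    ])
    def test_exponential_window(self, dt, expected):
        p = STDPParams(A_plus=0.01, A_minus=-0.01, tau_plus=5, tau_minus=5)
        assert stdp_delta(dt, p) == pytest.approx(expected)

    def test_silent_neighbor_contributes_nothing(self):
        assert stdp_delta(math.nan, STDPParams()) == 0.0


class TestSTDPUpdate:
    def test_ppt_input_is_exact_fixed_point(self):
        s = make_structure([1.06, 1.09, 1.12], [0.4, 0.4, 0.4])
        lat = 1.0 / (s.w_in - 1.0)
        x = ParallelSpikeTrain(30.0 - lat)
        out = stdp_update(s, x, STDPParams())
        assert np.array_equal(out.w_in, s.w_in)

    def test_two_branch_hand_evaluation(self):
        s = make_structure([1.08, 1.08], [0.6, 0.6])
        out = stdp_update(s, train_of(0.0, 2.5), STDPParams())
        dw = 0.01 * math.exp(-0.5)
        # the early-firing branch is depressed, the late one potentiated
        assert out.w_in - s.w_in == pytest.approx([-dw, +dw])

    def test_repeated_presentation_recovers_intervals(self):
        s = make_structure([1.08, 1.08, 1.08], [0.4, 0.4, 0.4])
        x = train_of(0.0, 4.0, 1.0)
        p = STDPParams(A_plus=0.01, A_minus=-0.01, tau_plus=5, tau_minus=5)
        trained, log = train_structure(s, [x], p, epochs=500, stop_tol=0.5)
        assert log.converged and log.presentations <= 500
        assert ppt(trained) == pytest.approx(x.intervals(), abs=0.5)


class TestTrainStructure:
    def test_zero_amplitude_changes_nothing(self):
        s = make_structure([1.08, 1.10], [0.6, 0.6])
        p = STDPParams(A_plus=0.0, A_minus=0.0)
        trained, _ = train_structure(s, [train_of(0.0, 3.0)], p, epochs=20)
        assert np.array_equal(trained.w_in, s.w_in)

    def test_empty_dataset_rejected(self):
        s = make_structure([1.08, 1.10], [0.6, 0.6])
        with pytest.raises(ValueError):
            train_structure(s, [], STDPParams())

    def test_jittered_clusters_recover_template(self):
        """Two interleaved jittered copies of one template (sigma = 1 ms)
        drive the PPT within 1 ms of the template intervals."""
        tpl = ClassTemplate(intervals=(5.0, -3.0), jitter_sd=1.0)
        trials = gen_trials(tpl, 60, seed=7)
        s = make_structure([1.08] * 3, [0.4] * 3)
        p = STDPParams(A_plus=0.005, A_minus=-0.005)
        trained, _ = train_structure(s, trials, p, epochs=10, shuffle=True,
                                     seed=3, average=True)
        assert ppt(trained) == pytest.approx(tpl.intervals, abs=1.0)


class TestInvariants:
    def test_recognition_translation_invariance(self, two_branch):
        r0 = recognize(two_branch, train_of(0.0, 2.5))
        r1 = recognize(two_branch, train_of(40.0, 42.5))
        assert r0.fired == r1.fired
        assert r1.Sp_M == pytest.approx(r0.Sp_M, abs=1e-9)
        assert r1.t_spike - r0.t_spike == pytest.approx(40.0, abs=1e-9)

    def test_higher_decay_is_never_more_permissive(self):
        """Raising the target decay Ld only makes the structure more
        selective: a rejected train never becomes recognised."""
        for lag in (0.0, 1.0, 3.0, 6.0, 12.0):
            fired = []
            for Ld in (0.005, 0.02, 0.05, 0.08, 0.15):
                s = make_structure([1.08, 1.08], [0.6, 0.6], Ld=Ld)
                fired.append(recognize(s, train_of(0.0, lag)).fired)
            # once recognition is lost it never comes back as Ld grows
            assert fired == sorted(fired, reverse=True)

    def test_single_update_moves_lag_toward_zero(self):
        """One STDP step shrinks the delay-layer lag whenever the lag
        dominates the update step (fixed-amplitude updates overshoot
        below that scale)."""
        for A in (0.001, 0.002, 0.005):
            for tau in (2.0, 5.0, 10.0):
                for lag in (2.0, 5.0, 10.0):
                    s = make_structure([1.08, 1.08], [0.6, 0.6])
                    p = STDPParams(A_plus=A, A_minus=-A,
                                   tau_plus=tau, tau_minus=tau)
                    x = train_of(0.0, lag)
                    before = delay_layer_outputs(s, x)
                    after = delay_layer_outputs(stdp_update(s, x, p), x)
                    b = before.neighbor_lag(1, 0)
                    a = after.neighbor_lag(1, 0)
                    assert abs(a) < abs(b)
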