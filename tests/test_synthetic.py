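"""Design conservation, determinism, and generative properties of the
synthetic-observer session generators."""

import numpy as np
import pandas as pd
import pytest

import gazebias.synthetic as syn


class TestDigits:
    def test_high_value_distribution(self, rng):
        d = syn.sample_digit("high", rng, size=100_000)
        frac = np.mean(d > 5)
        assert 0.70 <= frac <= 0.80
        vals, counts = np.unique(d, return_counts=True)
        assert vals[np.argmax(counts)] == 7

    def test_low_value_distribution(self, rng):
        d = syn.sample_digit("low", rng, size=100_000)
        assert 0.20 <= np.mean(d > 5) <= 0.30
        vals, counts = np.unique(d, return_counts=True)
        assert vals[np.argmax(counts)] == 3

    def test_five_never_emitted(self, rng):
        d = syn.sample_digit("high", rng, size=50_000)
        assert 5 not in d
        digits, p = syn.digit_distribution("low")
        assert 5 not in digits

    def test_exact_75_25_calibration(self):
        digits, p = syn.digit_distribution("high")
        assert p[digits > 5].sum() == pytest.approx(0.75, abs=1e-9)

    def test_unknown_condition_rejected(self, rng):
        with pytest.raises(ValueError):
            syn.sample_digit("medium", rng)


class TestExp1:
    def test_printed_trial_architecture(self):
        sess = syn.gen_exp1_session(syn.ObserverExp1(),
                                    syn.SessionSpec(1, seed=0))
        assert len(sess.trials) == 500
        assert len(sess.em_trials) == 400
        attn = sess.attention_trials
        assert len(attn) == 100
        assert attn.attn_location.value_counts().to_dict() == \
            {"high": 50, "low": 50}
        # trial types are interleaved, not blocked
        order = (sess.trials.trial_type == "attention").to_numpy()
        assert order[:100].sum() > 0 and order[-100:].sum() > 0

    def test_determinism(self):
        a = syn.gen_exp1_session(syn.ObserverExp1(), syn.SessionSpec(1, seed=7))
        b = syn.gen_exp1_session(syn.ObserverExp1(), syn.SessionSpec(1, seed=7))
        pd.testing.assert_frame_equal(a.trials, b.trials)

    def test_scores_follow_printed_rule(self):
        sess = syn.gen_exp1_session(syn.ObserverExp1(),
                                    syn.SessionSpec(1, seed=3))
        em = sess.em_trials
        wrong = em[~em.correct.astype(bool)]
        assert (wrong.score == -5).all()
        right_absent = em[em.correct.astype(bool) & ~em.digit_present.astype(bool)]
        assert (right_absent.score == 5).all()
        right_present = em[em.correct.astype(bool) & em.digit_present.astype(bool)]
        assert (right_present.score == right_present.digit_value).all()

    def test_digit_presence_independent_per_disc(self):
        sess = syn.gen_exp1_session(syn.ObserverExp1(),
                                    syn.SessionSpec(1, seed=11))
        em = sess.em_trials
        tab = pd.crosstab(em.digit_present.astype(bool),
                          em.digit_present_other.astype(bool))
        # both discs near 50% and roughly independent
        assert abs(em.digit_present.astype(bool).mean() - 0.5) < 0.08
        chi = ((tab - tab.values.sum() / 4) ** 2 / (tab.values.sum() / 4)).values.sum()
        assert chi < 15

    def test_non_integer_trial_counts_rejected(self):
        with pytest.raises(ValueError):
            syn.SessionSpec(1, overrides={"n_em_trials": 10.5})


class TestExp2:
    def test_block_design_counts(self):
        sess = syn.gen_exp2_session(syn.ObserverExp2(),
                                    syn.SessionSpec(2, seed=0),
                                    with_traces=False)
        for block in ("unbiased", "biased"):
            blk = sess.design[sess.design.block == block]
            assert len(blk) == 216
            counts = blk.comparison.value_counts()
            for v in (7.5, 8.0, 8.5):
                assert counts[v] == 36
            for v in (4, 6, 7, 9, 10, 12):
                assert counts[float(v)] == 18
            # order and durations fully balanced within velocity
            g = blk.groupby(["comparison", "order"]).size()
            assert set(g.loc[7.5]) == {18} and set(g.loc[4.0]) == {9}
            assert set(blk.dur_first) == {540, 720, 900}

    def test_ideal_observer_always_correct(self):
        obs = syn.ObserverExp2(sensory_noise_sd=0.0, motor_noise_sd=0.0,
                               pursuit_gain=1.0)
        sess = syn.gen_exp2_session(obs, syn.SessionSpec(2, seed=1),
                                    with_traces=False)
        des = sess.design[sess.design.comparison != 8.0]
        expected = des.comparison > 8.0
        assert (des.report_comparison_faster == expected).all()

    def test_pure_response_bias_dissociates(self):
        """Closed form of the generating model: response bias shifts the
        report decision but leaves the perceived velocities untouched."""
        obs = syn.ObserverExp2(response_bias=2.0)
        sess = syn.gen_exp2_session(obs, syn.SessionSpec(2, seed=2),
                                    reward_order="first", with_traces=False)
        biased = sess.design[sess.design.block == "biased"]
        unb = sess.design[sess.design.block == "unbiased"]
        # perceived velocities (the pursuit drive) are unbiased in both blocks
        assert abs((biased.perceived_first - biased.v_first).mean()) < 0.2
        # reports in the biased block favor the first interval
        assert biased.report_first_faster.mean() > unb.report_first_faster.mean() + 0.2

    def test_determinism(self):
        a = syn.gen_exp2_session(syn.ObserverExp2(), syn.SessionSpec(2, seed=5),
                                 reward_order="first", with_traces=True)
        b = syn.gen_exp2_session(syn.ObserverExp2(), syn.SessionSpec(2, seed=5),
                                 reward_order="first", with_traces=True)
        pd.testing.assert_frame_equal(a.design, b.design)
        np.testing.assert_array_equal(a.traces[0][0].x, b.traces[0][0].x)

    def test_durations_outside_printed_set_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            syn.gen_exp2_session(syn.ObserverExp2(),
                                 syn.SessionSpec(2, overrides={
                                     "durations": (540, 1000)}),
                                 with_traces=False)

    def test_step_ramp_geometry(self):
        """Target steps 1 deg left then ramps rightward; pursuit onset
        after the latency."""
        obs = syn.ObserverExp2(motor_noise_sd=0.0)
        rng = np.random.default_rng(0)
        tr = syn._pursuit_trace(rng, obs, 8.0, 8.0, 720)
        pre = tr.x[tr.t < obs.pursuit_latency]
        assert np.abs(pre).max() < 1e-9          # eye holds fixation
        late = tr.x[(tr.t > 600) & (tr.t < 720)]
        assert late[-1] > late[0]                # rightward pursuit


class TestExp3:
    def test_printed_trial_count_and_phases(self):
        sess = syn.gen_exp3_session(syn.ObserverExp3(),
                                    syn.SessionSpec(3, seed=0))
        assert len(sess.trials) == 34
        tr = sess.trials[0]
        assert tr.phase_bounds[0] == 8000
        assert set(tr.instructed) == {"a", "b"}
        # the final 2500 ms of each instructed phase is the hold
        assert set(tr.hold_positions) == {"a", "b"}

    def test_zero_reversal_rate_yields_no_reversals(self):
        obs = syn.ObserverExp3(reversal_rate=0.0)
        sess = syn.gen_exp3_session(obs, syn.SessionSpec(3, seed=1))
        assert all(t.reversal_times.size == 0 for t in sess.trials)

    def test_gaze_approaches_diagnostic_point_before_flip(self):
        obs = syn.ObserverExp3(gaze_lead=400.0, fixation_jitter_sd=0.2)
        sess = syn.gen_exp3_session(obs, syn.SessionSpec(3, seed=2))
        pre, post = [], []
        for t in sess.trials:
            for rt, to in zip(t.reversal_times, t.reversal_to):
                if rt < 1500 or rt > 6500:
                    continue
                pt = obs.diagnostic_point_a if to == "a" else obs.diagnostic_point_b
                d = np.hypot(t.trace.x - pt[0], t.trace.y - pt[1])
                i = int(rt)
                pre.append(d[i - 1200:i - 800].mean())   # before gaze shift
                post.append(d[i - 50:i + 50].mean())     # around the flip
        assert np.mean(post) < np.mean(pre) - 0.5

    def test_determinism(self):
        a = syn.gen_exp3_session(syn.ObserverExp3(), syn.SessionSpec(3, seed=9))
        b = syn.gen_exp3_session(syn.ObserverExp3(), syn.SessionSpec(3, seed=9))
        np.testing.assert_array_equal(a.trials[5].trace.x, b.trials[5].trace.x)
        np.testing.assert_array_equal(a.trials[5].reversal_times,
                                      b.trials[5].reversal_times)


class TestExp4:
    def test_printed_trial_architecture(self):
        sess = syn.gen_exp4_session(syn.ObserverExp4(),
                                    syn.SessionSpec(4, seed=0))
        assert len(sess.illusion) == 40
        assert len(sess.composite) == 560
        per_fix = sess.composite.fixation.value_counts()
        assert per_fix.to_dict() == {"a": 280, "b": 280}
        for fix in ("a", "b"):
            blk = sess.composite[sess.composite.fixation == fix]
            counts = blk.proportion.value_counts()
            for p in (0.42, 0.48, 0.5, 0.52, 0.58):
                assert counts[p] == 40
            for p in (0.2, 0.33, 0.66, 0.8):
                assert counts[p] == 20
        # illusion block: each stimulus 10x, 5 per fixation
        g = sess.illusion.groupby(["stimulus", "fixation"]).size()
        assert set(g) == {5}

    def test_equal_pses_give_no_fixation_effect(self):
        obs = syn.ObserverExp4(pse_fix_a=0.46, pse_fix_b=0.46)
        sess = syn.gen_exp4_session(obs, syn.SessionSpec(4, seed=1))
        rates = sess.composite.groupby("fixation").report_face.mean()
        assert abs(rates["a"] - rates["b"]) < 0.06

    def test_determinism(self):
        a = syn.gen_exp4_session(syn.ObserverExp4(), syn.SessionSpec(4, seed=2))
        b = syn.gen_exp4_session(syn.ObserverExp4(), syn.SessionSpec(4, seed=2))
        pd.testing.assert_frame_equal(a.composite, b.composite)
        pd.testing.assert_frame_equal(a.illusion, b.illusion)


class TestCohort:
    def test_deterministic_and_respects_bounds(self):
        a = syn.sample_cohort(syn.ObserverExp2(), 20, seed=3)
        b = syn.sample_cohort(syn.ObserverExp2(), 20, seed=3)
        assert a == b
        assert all(0 < o.pursuit_gain <= 1.2 for o in a)
        assert all(80 <= o.pursuit_latency <= 300 for o in a)

    def test_between_override_freezes_parameters(self):
        cohort = syn.sample_cohort(syn.ObserverExp4(), 5, seed=1, between={})
        assert all(o == syn.ObserverExp4() for o in cohort)


class TestObserverValidation:
    @pytest.mark.parametrize("cls,kw", [
        (syn.ObserverExp1, {"endpoint_sd": -1.0}),
        (syn.ObserverExp1, {"attn_threshold_low": 0.95}),
        (syn.ObserverExp1, {"lapse_rate": 0.5}),
        (syn.ObserverExp2, {"pursuit_gain": 1.5}),
        (syn.ObserverExp2, {"pursuit_latency": 10.0}),
        (syn.ObserverExp3, {"gaze_lead": -5.0}),
        (syn.ObserverExp4, {"pse_fix_a": 1.2}),
    ])
    def test_invariants_enforced(self, cls, kw):
        with pytest.raises(ValueError):
            cls(**kw)
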