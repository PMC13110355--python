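"""Velocity computation, saccade detection/excision, and pursuit summaries."""

import numpy as np
import pytest

from gazebias.pursuit import (DETECTION_FILTER, EyeTrace, SaccadeEvent,
                              VelocityTrace, desaccade, detect_saccades,
                              differentiate_and_filter, mean_pursuit_velocity,
                              oculometric_decision, running_average,
                              saccade_endpoint)


def make_trace(x, t0=0.0, y=None, markers=None):
    x = np.asarray(x, float)
    t = t0 + np.arange(x.size, dtype=float)
    return EyeTrace(t=t, x=x, y=np.zeros_like(x) if y is None else y,
                    markers=markers or {})


def saccade_waveform(n=1500, onset=700, amplitude=3.0, peak_v=200.0):
    """Raised-cosine saccade of known amplitude/peak velocity on a flat trace."""
    dur = int(round(2 * amplitude / peak_v * 1000))          # ms
    v = np.zeros(n)
    pulse = 1 - np.cos(2 * np.pi * np.arange(dur) / dur)
    pulse *= amplitude / (pulse.sum() * 1e-3)
    v[onset:onset + dur] = pulse
    x = np.cumsum(v) * 1e-3
    return make_trace(x), v, onset, dur


class TestDifferentiateAndFilter:
    def test_ramp_velocity(self):
        tr = make_trace(8.0 * np.arange(1000) / 1000.0)
        vel = differentiate_and_filter(tr)
        assert np.all(np.abs(vel.v[50:-50] - 8.0) < 0.01)

    def test_constant_position_zero_velocity(self):
        vel = differentiate_and_filter(make_trace(np.full(600, 2.5)))
        assert np.allclose(vel.v, 0.0, atol=1e-9)

    def test_high_frequency_attenuation(self):
        """Sinusoid well above the cutoff must be attenuated below 5%,
        matching the squared Butterworth transfer function."""
        f = 120.0
        t = np.arange(2000) / 1000.0
        tr = make_trace(0.5 * np.sin(2 * np.pi * f * t))
        vel = differentiate_and_filter(tr)
        inp_amp = 0.5 * 2 * np.pi * f          # analytic velocity amplitude
        out_amp = np.abs(vel.v[200:-200]).max()
        assert out_amp < 0.05 * inp_amp
        # oracle: |H|^2 for two cascaded 2nd-order Butterworths
        h2 = (1 / (1 + (f / 30) ** 4)) * (1 / (1 + (f / 40) ** 4))
        assert out_amp < 2 * h2 * inp_amp + 0.05 * inp_amp

    def test_zero_phase(self):
        """Cross-correlation peak between raw and filtered bump at lag 0."""
        x = np.zeros(1200)
        x[500:700] = np.hanning(200)
        tr = make_trace(np.cumsum(x) * 1e-3)
        vel = differentiate_and_filter(tr)
        xc = np.correlate(x - x.mean(), vel.v - vel.v.mean(), mode="full")
        assert abs(int(np.argmax(xc)) - (x.size - 1)) == 0

    def test_nonuniform_sampling_rejected(self):
        t = np.array([0.0, 1.0, 3.0, 4.0, 5.0] + list(np.arange(6, 300.0)))
        tr = EyeTrace(t=t, x=np.zeros(t.size), y=np.zeros(t.size))
        with pytest.raises(ValueError, match="uniform"):
            differentiate_and_filter(tr)

    def test_long_nan_gap_rejected_with_span(self):
        x = np.zeros(600)
        x[100:200] = np.nan
        with pytest.raises(ValueError, match="gaps"):
            differentiate_and_filter(make_trace(x))

    def test_short_gap_interpolated_and_flagged(self):
        x = 8.0 * np.arange(600) / 1000.0
        x[300:320] = np.nan
        vel = differentiate_and_filter(make_trace(x))
        assert vel.interpolated_mask[305]
        assert abs(vel.v[310] - 8.0) < 0.1


class TestDetectSaccades:
    def test_single_constructed_saccade(self):
        tr, v, onset, dur = saccade_waveform()
        vel = differentiate_and_filter(tr, DETECTION_FILTER)
        events = detect_saccades(vel, trace=tr)
        assert len(events) == 1
        assert abs(events[0].onset - onset) <= 5
        assert events[0].peak_velocity > 100
        assert events[0].amplitude == pytest.approx(3.0, abs=0.3)

    def test_subthreshold_noise_yields_no_events(self, rng):
        v = rng.normal(0, 5.0, 2000)
        vel = VelocityTrace(t=np.arange(2000.0), v=v,
                            interpolated_mask=np.zeros(2000, bool))
        assert detect_saccades(vel) == []

    def test_two_saccades_100ms_apart(self):
        tr1, v1, _, dur = saccade_waveform(onset=600)
        _, v2, _, _ = saccade_waveform(onset=600 + dur + 100)
        v = v1 + v2
        x = np.cumsum(v) * 1e-3
        tr = make_trace(x)
        vel = differentiate_and_filter(tr, DETECTION_FILTER)
        assert len(detect_saccades(vel, trace=tr)) == 2

    def test_empty_trace(self):
        vel = VelocityTrace(t=np.array([]), v=np.array([]),
                            interpolated_mask=np.array([], bool))
        assert detect_saccades(vel) == []

    def test_generator_injected_catchups_recovered(self):
        """>= 95% of catch-up saccades injected by the step-ramp generator
        are recovered with onset error <= 10 ms at default noise."""
        import gazebias.synthetic as syn
        obs = syn.ObserverExp2(pursuit_gain=0.85)   # low gain forces catch-ups
        rng = np.random.default_rng(7)
        injected = recovered = 0
        for k in range(60):
            tr = syn._pursuit_trace(rng, obs, 10.0, 10.0, 900)
            truth = [v for m, v in tr.markers.items()
                     if m.startswith("catchup_onset")]
            if not truth:
                continue
            vel = differentiate_and_filter(tr, DETECTION_FILTER)
            events = detect_saccades(vel, trace=tr)
            for t0 in truth:
                injected += 1
                if any(abs(ev.onset - t0) <= 10 for ev in events):
                    recovered += 1
        assert injected >= 40
        assert recovered / injected >= 0.95


class TestDesaccade:
    def _pursuit_with_spike(self):
        v = np.full(1000, 8.0)
        v[500:540] += 300.0
        vel = VelocityTrace(t=np.arange(1000.0), v=v,
                            interpolated_mask=np.zeros(1000, bool))
        ev = SaccadeEvent(onset=500, offset=539, amplitude=12.0,
                          peak_velocity=308.0, landing=(0, 0))
        return vel, ev

    def test_no_events_is_identity(self):
        vel, _ = self._pursuit_with_spike()
        out = desaccade(vel, [])
        np.testing.assert_array_equal(out.v, vel.v)

    def test_spike_region_restored_to_pursuit_level(self):
        vel, ev = self._pursuit_with_spike()
        out = desaccade(vel, [ev])
        assert np.abs(out.v[500:540] - 8.0).max() < 0.01
        assert out.interpolated_mask[500:540].all()

    def test_samples_outside_pads_never_change(self):
        vel, ev = self._pursuit_with_spike()
        out = desaccade(vel, [ev], pad=10)
        np.testing.assert_array_equal(out.v[:489], vel.v[:489])
        np.testing.assert_array_equal(out.v[551:], vel.v[551:])

    def test_overlapping_pads_merge_to_single_span(self):
        v = np.full(1000, 8.0)
        v[500:520] += 200
        v[525:545] += 200
        vel = VelocityTrace(t=np.arange(1000.0), v=v,
                            interpolated_mask=np.zeros(1000, bool))
        evs = [SaccadeEvent(500, 519, 4, 208, (0, 0)),
               SaccadeEvent(525, 544, 4, 208, (0, 0))]
        out = desaccade(vel, evs, pad=10)
        # merged: the whole 490..554 region is one linear (flat) stretch
        assert np.abs(out.v[490:555] - 8.0).max() < 1e-9


class TestPursuitSummaries:
    def test_constant_velocity_mean(self):
        vel = VelocityTrace(t=np.arange(1000.0), v=np.full(1000, 8.0),
                            interpolated_mask=np.zeros(1000, bool),
                            markers={"target_onset": 0.0})
        v, lowq = mean_pursuit_velocity(vel)
        assert v == pytest.approx(8.0)
        assert not lowq

    def test_window_is_half_open_after_onset(self):
        v = np.where(np.arange(1000) < 250, 2.0, 8.0)
        vel = VelocityTrace(t=np.arange(1000.0), v=v,
                            interpolated_mask=np.zeros(1000, bool),
                            markers={"target_onset": 0.0})
        assert mean_pursuit_velocity(vel)[0] == pytest.approx(8.0)

    def test_missing_marker_errors(self):
        vel = VelocityTrace(t=np.arange(1000.0), v=np.full(1000, 8.0),
                            interpolated_mask=np.zeros(1000, bool))
        with pytest.raises(ValueError, match="marker"):
            mean_pursuit_velocity(vel)

    def test_mostly_interpolated_window_flagged(self):
        mask = np.zeros(1000, bool)
        mask[250:450] = True
        vel = VelocityTrace(t=np.arange(1000.0), v=np.full(1000, 8.0),
                            interpolated_mask=mask,
                            markers={"target_onset": 0.0})
        v, lowq = mean_pursuit_velocity(vel)
        assert lowq and v == pytest.approx(8.0)


class TestOculometricDecision:
    def test_clear_cases(self):
        assert oculometric_decision(8.0, 9.1) is True
        assert oculometric_decision(8.0, 7.2) is False

    def test_tie_break_is_a_fair_seeded_coin(self):
        rng = np.random.default_rng(99)
        rate = np.mean([oculometric_decision(8.0, 8.0, rng)
                        for _ in range(10_000)])
        assert 0.48 <= rate <= 0.52

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            oculometric_decision(np.nan, 8.0)


class TestSaccadeEndpoint:
    def test_single_crossing_saccade(self):
        ev = SaccadeEvent(100, 140, 6.5, 300, landing=(6.2, 2.9))
        assert saccade_endpoint(None, [ev], midline_x=0.0) == (6.2, 2.9)

    def test_second_saccade_crosses(self):
        evs = [SaccadeEvent(100, 130, 3, 200, landing=(-1.0, 0.1)),
               SaccadeEvent(300, 340, 6, 300, landing=(6.1, -2.8))]
        assert saccade_endpoint(None, evs, midline_x=0.0) == (6.1, -2.8)

    def test_no_crossing_flags_invalid(self):
        evs = [SaccadeEvent(100, 130, 3, 200, landing=(-1.0, 0.1))]
        assert saccade_endpoint(None, evs, midline_x=0.0) is None


class TestRunningAverage:
    def test_constant_series_unchanged(self):
        out = running_average(np.full(100, 3.3), window_sd=5)
        np.testing.assert_allclose(out, 3.3)

    def test_impulse_mass_preserved_in_interior(self):
        x = np.zeros(201)
        x[100] = 1.0
        out = running_average(x, window_sd=4)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)
        assert out[100] == out.max()

    def test_zero_width_is_identity(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_array_equal(running_average(x, 0), x)
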