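"""SDF construction, baseline trend, response detection and metrics."""

import numpy as np
import pytest

from perispike.behavior import screen_trials
from perispike.config import AnalysisConfig
from perispike.responses import (analyze_direction, detect_response,
                                 fit_baseline, response_metrics,
                                 trial_traces_for_direction)
from perispike.responses import test_directionality as directionality
from perispike.sdf import SDFTrace, compute_sdf, gaussian_kernel, mean_sdf
from perispike.synth import SynthConfig, generate_session

AC = AnalysisConfig()


class TestSDF:
    def test_no_spikes_zero_trace(self):
        tr = compute_sdf([], 0.0, (-100, 100), AC)
        assert np.all(tr.values == 0)

    def test_single_spike_peak_closed_form(self):
        """Peak of a unit-mass Gaussian kernel: 1/(sigma*sqrt(2*pi))."""
        tr = compute_sdf([0.0], 0.0, (-200, 200), AC)
        peak = 1.0 / (0.025 * np.sqrt(2 * np.pi))
        i0 = 200  # grid position of t=0
        assert tr.values[i0] == pytest.approx(peak, rel=1e-3)
        np.testing.assert_allclose(tr.values[i0 - 50:i0],
                                   tr.values[i0 + 1:i0 + 51][::-1], rtol=1e-9)

    def test_mass_conservation(self, rng):
        spikes = np.sort(rng.uniform(0.2, 0.8, 40))
        tr = compute_sdf(spikes, 0.0, (0, 1000), AC)
        integral = tr.values.sum() / 1000.0
        assert integral == pytest.approx(40, rel=1e-3)

    def test_mean_sdf_and_min_trials(self):
        a = SDFTrace("movement_onset", np.arange(10), np.zeros(10), 1)
        b = SDFTrace("movement_onset", np.arange(10), np.full(10, 2.0), 1)
        m = mean_sdf([a, b])
        np.testing.assert_allclose(m.values, 1.0)
        with pytest.raises(ValueError):
            mean_sdf([a] * 9, min_trials=10)

    def test_mean_sdf_identical_traces_zero_sd(self):
        a = SDFTrace("movement_onset", np.arange(10), np.full(10, 3.0), 1)
        m = mean_sdf([a, a, a])
        np.testing.assert_allclose(m.per_point_sd, 0.0)

    def test_mismatched_grids_rejected(self):
        a = SDFTrace("movement_onset", np.arange(10), np.zeros(10), 1)
        b = SDFTrace("movement_onset", np.arange(1, 11), np.zeros(10), 1)
        with pytest.raises(ValueError):
            mean_sdf([a, b])


class TestBaseline:
    def _trace(self, values, start=-1000):
        g = np.arange(start, start + values.size)
        return SDFTrace("movement_onset", g, values, 20, flavor="mean")

    def test_flat_trace(self):
        tr = self._trace(np.full(1200, 50.0))
        b = fit_baseline(tr, -300, AC)
        assert b.slope == pytest.approx(0.0, abs=1e-9)
        assert b.intercept == pytest.approx(50.0)
        assert b.sd == pytest.approx(0.0, abs=1e-9)

    def test_exact_line_recovered(self):
        g = np.arange(-1000, 200)
        vals = 40.0 + 5.0 * (g / 1000.0)
        tr = self._trace(vals, start=-1000)
        b = fit_baseline(tr, -300, AC)
        assert b.slope == pytest.approx(5.0, rel=1e-6)
        assert b.sd == pytest.approx(0.0, abs=1e-6)
        assert b.project(-300) == pytest.approx(40.0 + 5 * (-0.3))

    def test_noise_sd_recovered(self, rng):
        sds = []
        for _ in range(30):
            g = np.arange(-1000, 0)
            vals = 40 + 5 * (g / 1000) + rng.normal(0, 2.0, g.size)
            sds.append(fit_baseline(self._trace(vals, -1000), -300, AC).sd)
        assert np.mean(sds) == pytest.approx(2.0, rel=0.25)

    def test_window_outside_trace_rejected(self):
        tr = self._trace(np.full(500, 10.0), start=-500)
        with pytest.raises(ValueError):
            fit_baseline(tr, -300, AC)  # needs [-1000, -300)


def _null_unit_traces(rng, n_trials=30, rate=40.0):
    """Null trials + traces without the generator overhead: Poisson spikes
    on a fixed window around movement onset."""
    from perispike.session import TrialEvents
    trials, traces = [], []
    for i in range(n_trials):
        rt = 0.35 + rng.normal(0, 0.05)
        md = 0.4 + rng.normal(0, 0.05)
        t0 = 100.0 * i
        tr = TrialEvents(i, "left", t0 - 6.0, t0 - rt, t0, t0 + md,
                         None, None, "correct")
        w0, w1 = -1400, 800
        nbins = w1 - w0 + 400
        hits = rng.random(nbins) < rate / 1000.0
        spikes = t0 + (w0 - 200 + np.flatnonzero(hits) + 0.5) / 1000.0
        traces.append(compute_sdf(spikes, t0, (w0, w1), AC))
        trials.append(tr)
    return trials, traces


class TestDetection:
    def test_null_units_rarely_significant(self, rng):
        """Omnibus false-positive control on response-free units."""
        n_fp = 0
        n_units = 40
        for _ in range(n_units):
            trials, traces = _null_unit_traces(rng)
            prof = detect_response(traces, trials, AC)
            n_fp += prof.rtype != "none"
        assert n_fp / n_units <= 0.05

    def test_planted_increase_detected_with_onset(self, responding_session):
        session, gt = responding_session
        metrics = screen_trials(session.trials, AC, "pre")
        valid = [t for t, m in zip(session.trials, metrics) if m.valid]
        prof = analyze_direction(session, session.units[0], "left", valid, AC)
        assert prof.rtype == "incr"
        # true onset: 150 ms before movement onset, rise ~2 sigma earlier
        assert -150 - 2.5 * 80 <= prof.onset_latency_move <= -150 + 80

    def test_planted_decrease_then_increase_poly_di(self):
        cfg = SynthConfig(seed=77, n_trials=80, baseline_rate=60.0,
                          response_type="poly_di", response_amp=50.0,
                          response_sigma=0.08, lock_lambda=1.0,
                          onset_offset=-0.1, refractory=0.002)
        session, _ = generate_session(cfg)
        metrics = screen_trials(session.trials, AC, "pre")
        valid = [t for t, m in zip(session.trials, metrics) if m.valid]
        prof = analyze_direction(session, session.units[0], "left", valid, AC)
        assert prof.rtype == "poly_di"
        assert prof.segments[0].sign == -1

    def test_min_trials_enforced(self, responding_session):
        session, _ = responding_session
        metrics = screen_trials(session.trials, AC, "pre")
        valid = [t for t, m in zip(session.trials, metrics) if m.valid]
        few = [t for t in valid if t.target == "left"][:9]
        assert analyze_direction(session, session.units[0], "left", few,
                                 AC) is None

    def test_translation_invariance(self):
        """Shifting all events and spikes by a constant leaves the
        detected profile unchanged."""
        cfg = SynthConfig(seed=88, n_trials=60, baseline_rate=40.0,
                          response_type="incr", response_amp=55.0,
                          response_sigma=0.09, lock_lambda=1.0,
                          onset_offset=-0.1)
        session, _ = generate_session(cfg)
        metrics = screen_trials(session.trials, AC, "pre")
        valid = [t for t, m in zip(session.trials, metrics) if m.valid]
        p1 = analyze_direction(session, session.units[0], "left", valid, AC)

        from copy import deepcopy
        shifted = deepcopy(session)
        dt = 1000.0
        for t in shifted.trials:
            for f in ("sphp_start", "go_cue", "movement_onset",
                      "movement_offset", "reward", "return_complete"):
                v = getattr(t, f)
                if v is not None:
                    setattr(t, f, v + dt)
        shifted.units[0].spike_times = shifted.units[0].spike_times + dt
        valid2 = [t for t in shifted.trials
                  if t.trial_index in {v.trial_index for v in valid}]
        p2 = analyze_direction(shifted, shifted.units[0], "left", valid2, AC)
        assert p1.rtype == p2.rtype
        assert p1.onset_latency_move == p2.onset_latency_move
        assert p1.magnitude == pytest.approx(p2.magnitude, rel=1e-9)


class TestMetrics:
    def _noiseless_bump_profile(self, amp, sigma_ms):
        """Mean trace = flat 40 sp/s baseline + Gaussian bump convolved
        with the SDF kernel (closed-form variance sum)."""
        g = np.arange(-1000, 600)
        k_sig = 25.0
        obs_sig = np.hypot(sigma_ms, k_sig)
        bump = amp * (sigma_ms / obs_sig) * np.exp(
            -0.5 * ((g - 100) / obs_sig) ** 2)
        vals = 40.0 + bump
        tr = SDFTrace("movement_onset", g, vals, 40, flavor="mean")
        trend = fit_baseline(tr, -300, AC)
        return tr, trend, obs_sig

    def test_bump_magnitude_and_fwhm_closed_form(self):
        from perispike.responses import ResponseProfile, ResponseSegment
        amp, sig = 10.0, 50.0
        tr, trend, obs_sig = self._noiseless_bump_profile(amp, sig)
        prof = ResponseProfile("u", "left", "incr",
                               [ResponseSegment(0, 200, 1)], trend=trend)
        prof = response_metrics(tr, trend, prof, AC)
        expect_mag = amp * sig / obs_sig
        assert prof.magnitude == pytest.approx(expect_mag, rel=0.10)
        assert prof.fwhm == pytest.approx(2.355 * obs_sig, rel=0.15)
        assert not prof.fwhm_truncated

    def test_mirrored_decrease_symmetric(self):
        from perispike.responses import ResponseProfile, ResponseSegment
        g = np.arange(-1000, 600)
        bump = 12.0 * np.exp(-0.5 * ((g - 100) / 60.0) ** 2)
        up = SDFTrace("movement_onset", g, 50 + bump, 40, flavor="mean")
        dn = SDFTrace("movement_onset", g, 50 - bump, 40, flavor="mean")
        tu = fit_baseline(up, -300, AC)
        td = fit_baseline(dn, -300, AC)
        pu = response_metrics(up, tu, ResponseProfile(
            "u", "left", "incr", [ResponseSegment(0, 200, 1)]), AC)
        pd = response_metrics(dn, td, ResponseProfile(
            "u", "left", "decr", [ResponseSegment(0, 200, -1)]), AC)
        assert pd.magnitude == pytest.approx(-pu.magnitude, rel=1e-6)
        assert pd.fwhm == pu.fwhm

    def test_magnitude_monotone_in_amplitude(self):
        mags = []
        for amp in (5.0, 10.0, 20.0, 40.0):
            from perispike.responses import ResponseProfile, ResponseSegment
            tr, trend, _ = self._noiseless_bump_profile(amp, 60.0)
            p = response_metrics(tr, trend, ResponseProfile(
                "u", "left", "incr", [ResponseSegment(0, 200, 1)]), AC)
            mags.append(p.magnitude)
        assert np.all(np.diff(mags) > 0)


class TestDirectionality:
    def test_planted_gain_difference_detected(self):
        cfg = SynthConfig(seed=99, n_trials=80, baseline_rate=40.0,
                          response_type="incr", response_amp=60.0,
                          response_sigma=0.1, lock_lambda=1.0,
                          onset_offset=-0.1,
                          direction_gain={"left": 2.0, "right": 0.5})
        session, _ = generate_session(cfg)
        metrics = screen_trials(session.trials, AC, "pre")
        valid = [t for t, m in zip(session.trials, metrics) if m.valid]
        profiles = {d: analyze_direction(session, session.units[0], d,
                                         valid, AC)
                    for d in ("left", "right")}
        tbd = {d: [t for t in valid if t.target == d]
               for d in ("left", "right")}
        d300, dwhole = directionality(session.units[0], profiles, tbd, AC)
        assert dwhole
        assert d300

    def test_identical_gains_mostly_not_directional(self):
        n_dir = 0
        n_units = 15
        for i in range(n_units):
            cfg = SynthConfig(seed=1000 + i, n_trials=60, baseline_rate=40.0,
                              response_type="incr", response_amp=55.0,
                              response_sigma=0.1, lock_lambda=1.0,
                              onset_offset=-0.1)
            session, _ = generate_session(cfg)
            metrics = screen_trials(session.trials, AC, "pre")
            valid = [t for t, m in zip(session.trials, metrics) if m.valid]
            profiles = {d: analyze_direction(session, session.units[0], d,
                                             valid, AC)
                        for d in ("left", "right")}
            tbd = {d: [t for t in valid if t.target == d]
                   for d in ("left", "right")}
            _, dwhole = directionality(session.units[0], profiles, tbd, AC)
            n_dir += dwhole
        assert n_dir / n_units <= 0.2
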