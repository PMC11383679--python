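"""Single-trial onsets, event locking / ELI, dispersion, de-jittering."""

import numpy as np
import pytest

from perispike.config import AnalysisConfig
from perispike.responses import fit_baseline
from perispike.sdf import SDFTrace, gaussian_kernel, mean_sdf
from perispike.session import TrialEvents
from perispike.synth import SynthConfig, noiseless_trial_sdfs
from perispike.timing import (TrialOnset, dejitter, event_locking,
                              single_trial_onset, timing_dispersion)

AC = AnalysisConfig()


def _step_trace(t_star_ms, lo=30.0, hi=60.0, w=(-900, 900)):
    """Noiseless rate step smoothed by the SDF kernel, movement-aligned."""
    k = gaussian_kernel(AC.sdf_sigma)
    r = (k.size - 1) // 2
    g = np.arange(w[0] - r, w[1] + r)
    rate = np.where(g < t_star_ms, lo, hi).astype(float)
    vals = np.convolve(rate, k, mode="same")[r:r + (w[1] - w[0])]
    return SDFTrace("movement_onset", np.arange(*w), vals, 1)


def _trial(rt=0.4, md=0.5, idx=0, t0=100.0):
    return TrialEvents(idx, "left", t0 - rt - 5.0, t0 - rt, t0, t0 + md,
                       None, None, "correct")


class TestStepOnset:
    @pytest.mark.parametrize("t_star", [-250, -120, 0, 150, 320])
    def test_noiseless_step_recovered(self, t_star):
        trial = _trial(rt=0.4, md=0.5)
        tr = _step_trace(t_star)
        o = single_trial_onset(tr, trial, "incr", AC)
        assert o.detected
        assert o.onset_rel_move == pytest.approx(t_star, abs=2)

    def test_decrease_recovered_via_inversion(self):
        trial = _trial()
        k = gaussian_kernel(AC.sdf_sigma)
        r = (k.size - 1) // 2
        g = np.arange(-900 - r, 900 + r)
        rate = np.where(g < -100, 60.0, 30.0)
        vals = np.convolve(rate, k, mode="same")[r:r + 1800]
        tr = SDFTrace("movement_onset", np.arange(-900, 900), vals, 1)
        o = single_trial_onset(tr, trial, "decr", AC)
        assert o.detected and o.onset_rel_move == pytest.approx(-100, abs=2)

    def test_constant_trace_undetected(self):
        tr = SDFTrace("movement_onset", np.arange(-900, 900),
                      np.full(1800, 40.0), 1)
        o = single_trial_onset(tr, _trial(), "incr", AC)
        assert not o.detected

    def test_too_few_spikes_undetected(self):
        tr = _step_trace(0)
        o = single_trial_onset(tr, _trial(), "incr", AC, n_spikes_in_span=1)
        assert not o.detected


def _locking_inputs(lam, n=50, jitter=0.0, seed=13):
    """Trials with variable RT and analytically placed onsets."""
    rng = np.random.default_rng(seed)
    trials, onsets = [], []
    for i in range(n):
        rt = 0.35 + rng.normal(0, 0.05)
        t0 = 50.0 * (i + 1)
        tr = _trial(rt=rt, md=0.45, idx=i, t0=t0)
        on = tr.go_cue + 0.15 + lam * rt + rng.normal(0, jitter)
        trials.append(tr)
        onsets.append(TrialOnset(
            trial_index=i, onset=on,
            onset_rel_cue=1000 * (on - tr.go_cue),
            onset_rel_move=1000 * (on - tr.movement_onset),
            fit_sse=0.0, detected=True))
    return trials, onsets


class TestEventLocking:
    def test_perfect_cue_locking(self):
        trials, onsets = _locking_inputs(lam=0.0)
        r = event_locking(onsets, trials, AC)
        assert r.slope_cue_resp == pytest.approx(0.0, abs=1e-9)
        assert r.slope_resp_mvt == pytest.approx(1.0, abs=1e-9)
        assert r.category == "cue_locked"
        assert r.eli == pytest.approx(-1.0, abs=1e-9)

    def test_perfect_movement_locking(self):
        trials, onsets = _locking_inputs(lam=1.0)
        r = event_locking(onsets, trials, AC)
        assert r.category == "move_locked"
        assert r.eli == pytest.approx(1.0, abs=1e-9)

    def test_midpoint_locking(self):
        trials, onsets = _locking_inputs(lam=0.5)
        r = event_locking(onsets, trials, AC)
        assert r.eli == pytest.approx(0.0, abs=1e-9)
        assert r.category == "intermediate"

    @pytest.mark.parametrize("lam", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_slope_sum_identity(self, lam):
        trials, onsets = _locking_inputs(lam=lam, jitter=0.03)
        r = event_locking(onsets, trials, AC)
        assert r.slope_cue_resp + r.slope_resp_mvt == pytest.approx(1.0,
                                                                    abs=1e-6)

    @pytest.mark.parametrize("lam", [0.0, 0.25, 0.5])
    def test_eli_antisymmetric_in_lambda(self, lam):
        trials_a, onsets_a = _locking_inputs(lam=lam)
        trials_b, onsets_b = _locking_inputs(lam=1.0 - lam)
        ra = event_locking(onsets_a, trials_a, AC)
        rb = event_locking(onsets_b, trials_b, AC)
        assert ra.eli == pytest.approx(-rb.eli, abs=1e-6)

    def test_insufficient_trials_rejected(self):
        trials, onsets = _locking_inputs(lam=0.5, n=4)
        with pytest.raises(ValueError):
            event_locking(onsets, trials, AC)


class TestDispersion:
    def test_affine_onsets_zero_iqr(self):
        trials, onsets = _locking_inputs(lam=0.3)
        assert timing_dispersion(onsets, trials) == pytest.approx(0.0,
                                                                  abs=1e-6)

    def test_uniform_jitter_iqr_oracle(self):
        """IQR of U(-w/2, w/2) residuals is w/2 (w = 80 ms)."""
        rng = np.random.default_rng(7)
        iqrs = []
        for rep in range(30):
            trials, onsets = _locking_inputs(lam=0.5, n=200,
                                             seed=100 + rep)
            for o, t in zip(onsets, trials):
                j = rng.uniform(-40.0, 40.0)
                o.onset += j / 1000.0
                o.onset_rel_cue += j
                o.onset_rel_move += j
            iqrs.append(timing_dispersion(onsets, trials))
        assert np.mean(iqrs) == pytest.approx(40.0, rel=0.15)

    def test_reference_event_irrelevant(self):
        """Residuals are identical whether latency is referenced to the cue
        or to movement, since RT is the regressor."""
        trials, onsets = _locking_inputs(lam=0.5, jitter=0.05)
        iqr_cue = timing_dispersion(onsets, trials)
        shifted = [TrialOnset(o.trial_index, o.onset, o.onset_rel_move,
                              o.onset_rel_move, o.fit_sse, detected=True)
                   for o in onsets]
        by = {t.trial_index: t for t in trials}
        for o in shifted:
            t = by[o.trial_index]
            o.onset_rel_cue = 1000 * (o.onset - t.movement_onset)
        iqr_move = timing_dispersion(shifted, trials)
        assert iqr_cue == pytest.approx(iqr_move, abs=1e-9)


class TestDejitter:
    def _bump_setup(self, jitter_sd, seed=9):
        cfg = SynthConfig(seed=seed, regime="pre", n_trials=40,
                          baseline_rate=40.0, response_type="incr",
                          response_amp=20.0, response_sigma=0.05,
                          lock_lambda=1.0, onset_offset=-0.15,
                          jitter_sd=jitter_sd)
        trials, traces, gt = noiseless_trial_sdfs(cfg, (-1300, 900))
        m = mean_sdf(traces)
        trend = fit_baseline(m, -600, AC)
        onsets = [single_trial_onset(tr, t, "incr", AC)
                  for tr, t in zip(traces, trials)]
        return trials, traces, m, trend, onsets

    def test_jittered_bumps_recovered(self):
        trials, traces, m, trend, onsets = self._bump_setup(jitter_sd=0.08)
        dj = dejitter(traces, onsets, trials, "incr", trend, AC)
        single_trial_mag = 20.0 * 50 / np.hypot(50, 25)
        event_mag = (m.values - trend.project(m.time_grid)).max()
        assert dj.magnitude == pytest.approx(single_trial_mag, rel=0.10)
        assert event_mag < 0.8 * dj.magnitude

    def test_zero_jitter_noop(self):
        trials, traces, m, trend, onsets = self._bump_setup(jitter_sd=0.0)
        dj = dejitter(traces, onsets, trials, "incr", trend, AC)
        event_mag = (m.values - trend.project(m.time_grid)).max()
        assert dj.magnitude == pytest.approx(event_mag, rel=0.02)

    def test_dejittered_magnitude_monotone_in_jitter(self):
        event_mags, dj_mags = [], []
        for j in (0.0, 0.04, 0.08):
            trials, traces, m, trend, onsets = self._bump_setup(jitter_sd=j)
            dj = dejitter(traces, onsets, trials, "incr", trend, AC)
            event_mags.append(
                (m.values - trend.project(m.time_grid)).max())
            dj_mags.append(dj.magnitude)
        # event-aligned magnitude shrinks with jitter; de-jittered does not
        assert event_mags[0] > event_mags[1] > event_mags[2]
        assert np.all(np.asarray(dj_mags) >= np.asarray(event_mags) - 1e-6)

    def test_planted_decrease_mirrors_increase(self):
        cfg_up = SynthConfig(seed=15, n_trials=40, baseline_rate=60.0,
                             response_type="incr", response_amp=20.0,
                             response_sigma=0.05, lock_lambda=1.0,
                             onset_offset=-0.15, jitter_sd=0.05)
        cfg_dn = SynthConfig(seed=15, n_trials=40, baseline_rate=60.0,
                             response_type="decr", response_amp=20.0,
                             response_sigma=0.05, lock_lambda=1.0,
                             onset_offset=-0.15, jitter_sd=0.05)
        out = {}
        for name, cfg in (("up", cfg_up), ("dn", cfg_dn)):
            trials, traces, _ = noiseless_trial_sdfs(cfg, (-1300, 900))
            m = mean_sdf(traces)
            trend = fit_baseline(m, -600, AC)
            rtype = "incr" if name == "up" else "decr"
            onsets = [single_trial_onset(tr, t, rtype, AC)
                      for tr, t in zip(traces, trials)]
            out[name] = dejitter(traces, onsets, trials, rtype, trend, AC)
        assert out["dn"].magnitude < 0
        assert abs(out["dn"].magnitude) == pytest.approx(out["up"].magnitude,
                                                         rel=0.05)

    def test_polyphasic_rejected(self):
        trials, traces, _, trend, onsets = self._bump_setup(jitter_sd=0.0)
        with pytest.raises(ValueError):
            dejitter(traces, onsets, trials, "poly_id", trend, AC)

    def test_zscored_variant(self):
        trials, traces, m, trend, onsets = self._bump_setup(jitter_sd=0.05)
        # noiseless traces have ~zero baseline variability across trials,
        # so z-scoring must refuse rather than divide by ~0
        with pytest.raises(ValueError):
            dejitter(traces, onsets, trials, "incr", trend, AC, zscore=True)


class TestZScoreOnSpikes:
    def test_zscored_magnitude_positive_for_increase(self,
                                                     responding_session):
        from perispike.behavior import screen_trials
        from perispike.responses import (analyze_direction,
                                         trial_traces_for_direction)
        session, _ = responding_session
        metrics = screen_trials(session.trials, AC, "pre")
        valid = [t for t, m in zip(session.trials, metrics) if m.valid]
        prof = analyze_direction(session, session.units[0], "left", valid,
                                 AC)
        trials, traces = trial_traces_for_direction(
            session, session.units[0], "left", valid, AC)
        onsets = [single_trial_onset(tr, t, prof.rtype, AC)
                  for tr, t in zip(traces, trials)]
        dj = dejitter(traces, onsets, trials, prof.rtype, prof.trend, AC,
                      zscore=True)
        assert dj.zscored_magnitude is not None
        assert dj.zscored_magnitude > 0
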