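# perispike

Peri-event single-unit spike-train analysis for task-aligned
electrophysiology — built for studies of basal-ganglia output (globus
pallidus internus) in a choice reaction-time reaching task, before and
after induction of parkinsonism, but applicable to any recording that
pairs sorted spike times with per-trial behavioral event times.

The package answers three families of questions:

1. **How does the neuron fire at rest?**  During pre-cue hold periods it
   measures the pooled firing rate, ISI coefficient of variation,
   Poisson-surprise bursts (natural-log surprise S ≥ 5, ≥ 4 spikes),
   shuffle-normalized oscillation spectra (512-ms Hann segments, 100
   ISI-shuffled surrogates, 150–250 Hz control band), and linear rate
   ramps.
2. **Does it respond around movement, and how?**  Single-trial spike
   density functions (Gaussian kernel, σ = 25 ms) are averaged per reach
   direction; runs of ≥ 60 ms where the across-trial rate departs from a
   trend-corrected baseline at omnibus p < 0.001 (Bonferroni over tested
   points) define responses, classified by the sign of the earliest run
   and quantified by onset latency, signed magnitude and full width at
   half-maximum change.
3. **When does the response start on each trial, and what is it locked
   to?**  A 200-ms step kernel fitted at 1-ms shifts yields per-trial
   onsets; regressing the cue→onset and onset→movement intervals on the
   reaction time RT gives two slopes that sum to 1 and the event-locking
   index

   ELI = (slope_cue→resp − slope_resp→mvt) / (slope_cue→resp + slope_resp→mvt),

   −1 for perfect cue locking, +1 for perfect movement locking.
   Realigning single-trial SDFs on their own response peaks
   ("de-jittering") recovers response magnitude and duration free of
   trial-to-trial timing jitter.

A synthetic-session generator with full ground truth (known baseline,
ramp, oscillation, bursts, response shape, locking parameter λ and
jitter) backs every stage with parameter-recovery tests; the recovered
ELI equals 2λ − 1 on noiseless data.

## Worked example

```python
import numpy as np
from perispike.config import AnalysisConfig
from perispike.synth import SynthConfig, generate_session
from perispike.behavior import screen_trials
from perispike.responses import analyze_direction, trial_traces_for_direction
from perispike.rest import summarize_rest
from perispike.timing import single_trial_onset, event_locking

cfg = SynthConfig(seed=42, regime="pre", n_trials=120, baseline_rate=55.0,
                  response_type="incr", response_amp=85.0,
                  response_sigma=0.06, lock_lambda=1.0, onset_offset=-0.12,
                  refractory=0.002)
session, truth = generate_session(cfg)
ac = AnalysisConfig()

rest = summarize_rest(session, session.units[0], ac, seed=0)
metrics = screen_trials(session.trials, ac, "pre")
valid = [t for t, m in zip(session.trials, metrics) if m.valid]
prof = analyze_direction(session, session.units[0], "left", valid, ac)
trials, traces = trial_traces_for_direction(session, session.units[0],
                                            "left", valid, ac)
st = session.units[0].spike_times
onsets = [single_trial_onset(tr, t, prof.rtype, ac,
                             n_spikes_in_span=int(np.sum(
                                 (st >= t.go_cue) & (st < t.movement_offset))))
          for t, tr in zip(trials, traces)]
lock = event_locking(onsets, trials, ac)
```

This prints, via the obvious f-strings:

```
rest: rate 52.0 sp/s, ISI CV 0.92, burstiness 0.014, ramp none
response: incr, onset -223 ms, magnitude 67.5 sp/s, FWHM 142 ms
locking: move_locked, ELI +0.90, slopes 0.95/0.05, residual IQR 66 ms
```

Reading: the unit rests near its configured 55 sp/s with Poisson-like
variability (CV ≈ 0.9) and negligible bursting; around movement it shows
an increase-type response whose detected onset (−223 ms, first
significant millisecond) precedes the planted bump center (−120 ms) by
roughly the rise of the smoothed bump; and because the response was
generated with λ = 1 (movement-locked), the cue→onset slope is ≈1, the
onset→movement slope ≈0, and the ELI is +0.90 with a residual timing IQR
of 66 ms.

## Analysis drivers

`analysis/` holds the numbered study scripts: `01_simulate_sessions.py`
draws pre- and post-state populations (bundles under `scratch/`,
manifest under `results/`), `02_run_pipeline.py` runs QC → behavior →
rest → responses → timing over them and writes stage tables under
`results/pipeline/<state>/`, and `03_population_comparison.py` produces
the population contrasts (rest measures by rank-sum, response-type ×
state contingency with adjusted residuals, ELI distribution shift by
Kolmogorov–Smirnov) under `results/population/`.

A CLI mirrors the stages (`perispike synth|behavior|rest|qc|pipeline`);
see `perispike --help`.  Sessions travel as plain-text bundles (a trials
table, one spike-time list per unit, ms precision) that round-trip
exactly; `docs/methods.md` documents every model and numerical choice.

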