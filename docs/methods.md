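# Methods

`perispike` implements a complete single-unit analysis chain for
task-aligned extracellular recordings: behavioral screening, resting-state
discharge characterization, perimovement response detection and
quantification from spike density functions (SDFs), single-trial
response-onset timing with event-locking regression, and de-jittered
response metrics.  It was built around a choice reaction-time (RT)
reaching task in which each trial begins with a 2–10 s uniform
start-position hold period (SPHP), followed by a go-cue, a reach to a
left or right target, and reward.  Analyses compare a neurologically
normal state ("pre") against a dopamine-depleted parkinsonian state
("post") with slowed behavior and altered pallidal discharge.

## Time base and SDFs

All times are seconds on a single session clock; spike stamps carry 1-ms
resolution, and every internal raster uses 1-ms bins with half-open
`[t, t+1 ms)` membership.  An SDF is the spike delta function convolved
with a unit-mass Gaussian kernel (σ = 25 ms, truncated at ±4σ and
renormalized), expressed in spikes/s.  A single spike therefore peaks at
1/(σ√2π) ≈ 15.96 sp/s, and a trace integrates to its spike count.
Spikes outside an analysis window still contribute through kernel tails,
so windows carry no edge deficit.

## Resting-state measures (SPHP)

* **Mean rate** — pooled: total spikes across all SPHPs over total SPHP
  duration (never a mean of per-segment rates).
* **ISI CV** — SD/mean of inter-spike intervals pooled *within*
  segments; intervals never span segment boundaries.
* **Bursts** — Poisson-surprise method.  A candidate is seeded by two
  consecutive ISIs shorter than half the unit's mean ISI, extended one
  spike at a time while surprise grows, then trimmed from the start.
  Because a candidate is anchored on its first spike, the surprise of an
  *n*-spike run spanning *T* is computed as
  S = −ln P(N ≥ n−1), N ~ Poisson(rate·T): the chance of the remaining
  n−1 spikes landing within *T*.  Acceptance requires n ≥ 4 and S ≥ 5
  (natural log; a log10 toggle exists).  This convention was fixed by a
  false-positive simulation: on homogeneous Poisson trains it yields a
  mean burstiness of ≈0.04, whereas scoring all *n* spikes combined with
  multi-spike lookahead maximization inflates the null to ≈0.15.
  Burstiness is the fraction of all SPHP spikes inside accepted bursts;
  the intra-burst rate is also reported normalized by the unit rate.
* **Oscillations** — shuffle-normalized spectra.  Each SPHP with ≥ 4
  spikes is cut into non-overlapping 512-ms windows; each window is
  binarized at 1 kHz, Hann-tapered, and periodogram-transformed
  (≈1.953-Hz bins, reported as 2-Hz resolution).  The primary spectrum
  (mean over windows) is divided by a control spectrum: the mean over
  100 surrogates built by order-permuting the pooled within-SPHP ISIs,
  reconstructing a train, laying it onto the original segment durations
  and re-segmenting identically.  The ratio hovers around 1 under
  stationarity and cancels refractory-period distortion.  Bins in
  4–100 Hz are significant when normalized power exceeds the
  150–250 Hz control-band mean plus z·SD, z the one-sided normal
  quantile for 0.05/51 (the published Bonferroni divisor for the tested
  points; configurable).  Contiguous significant runs collapse to their
  highest-power bin, assigned to theta (4–7.9), alpha (8–12), low beta
  (12.5–20), high beta (20.5–30) or gamma (30.5–100 Hz).
* **Ramps** — firing rate in 250-ms bins regressed on time from SPHP
  onset, pooled over segments; a sign is assigned at two-sided p < 0.05.
  The binning and the onset-referenced time axis are package choices; a
  hazard-rate reading would instead count backward from the go-cue, but
  for a linear fit the two differ only in per-segment intercepts.

## Perimovement responses

Single-trial SDFs aligned on movement onset are averaged per reach
direction (minimum 10 valid trials per direction).  The test window runs
from the across-trials median go-cue time to the median movement-offset
time.  Baseline is an OLS line fitted to the mean SDF over the 700 ms
ending at the test-window start; its residual SD summarizes baseline
variability, and the line is extrapolated ("trend projection") across
the test window so pre-movement rate ramps do not masquerade as
responses.

At every 1-ms point the across-trial single-trial SDF values are tested
against the trend projection (one-sample t-test; a z-versus-baseline-SD
variant is a config toggle).  A point is significant at
p < 0.001/N, N the number of tested points; maximal runs of ≥ 60
consecutive significant ms of constant sign become response segments.
Classification follows the sign of the earliest segment: one sign only →
increase/decrease; alternating signs → polyphasic +/− or −/+.

Metrics (initial phase only for polyphasic responses): onset latency =
first significant millisecond (movement- and optionally cue-aligned);
magnitude = signed extremum of (mean SDF − trend) within the initial
segment; duration = full width at half-maximum change (FWHM), the
contiguous same-sign region where the deviation stays ≥ half the
magnitude, flagged (not discarded) when truncated at the window edge.
Note the kernel widens and attenuates a true Gaussian rate bump of SD
σ_r and amplitude A to SD √(σ_r²+σ²) and amplitude A·σ_r/√(σ_r²+σ²);
recovery tests check against these closed forms.

Directionality uses two rank-sum tests of left- versus right-target
per-trial spike counts (α = 0.05): a 300-ms window starting at the
unit's earliest detected onset, and the whole go-cue-to-movement-offset
interval of each trial.

**Power.** With a 25-ms kernel, the per-point SD of a single-trial SDF
at baseline rate r is √(r/(2√π·σ)) ≈ 21 sp/s at 40 sp/s, so at 40
trials the per-point SEM is ≈3.3 sp/s and the Bonferroni threshold
demands sustained deviations of roughly 15–20 sp/s.  Detection is
therefore reliable for the large modulations typical of pallidal
neurons (tens of sp/s) and deliberately conservative for small bumps;
the false-positive suite verifies the conservative side (< 2% of null
units over 200 simulations).

## Single-trial timing

Only units with a significant mean-SDF response are analyzed, and the
mean-SDF response type guides the fit (decrease-led responses invert the
single-trial SDF first).  A 200-ms step kernel — 100 points at the
single-trial SDF minimum over the go-cue-to-movement-end search span,
then 100 points at its maximum — slides at 1-ms steps across the span;
the transition time minimizing the summed squared error is the trial's
response onset.  The kernel may overhang the span edges by up to 100 ms
with the SDF extended by its edge values; ties break earliest, boundary
hits are flagged, and trials with fewer than 2 spikes in the span or a
degenerate (min = max) kernel are marked undetected.

**Event locking.** Two OLS regressions on the identical trial set relate
the cue-to-onset interval and the onset-to-movement interval to the
behavioral RT.  Since the intervals sum to the RT, the slopes sum to 1
exactly (asserted to 1e-6).  "Significant positive" means two-sided
p < 0.05 *and* slope > 0; categories: only onset-to-movement significant
→ cue-locked; only cue-to-onset → move-locked; both → intermediate;
neither → indeterminate.  The event-locking index
ELI = (slope_cue−resp − slope_resp−mvt)/(slope_cue−resp + slope_resp−mvt)
runs from −1 (perfect cue locking) through 0 (midpoint covariation) to
+1 (perfect movement locking).  Conditioning caveat: the slope SE scales
as σ_onset/(σ_RT·√n), so with little RT variability (the fast pre-state,
SD ≈ 0.05 s) single-trial onset noise of ≈100 ms propagates into slope
noise of order 0.3–0.7 and individual ELIs scatter well beyond ±1; with
the slowed post-state RTs (SD ≈ 0.4 s) estimates are much tighter.

**Timing dispersion.** The IQR of residuals from regressing
cue-referenced onset latency on RT; residuals are algebraically
identical for movement-referenced latency since RT is the regressor.

**De-jittering** (monophasic responses only).  Per trial, the earliest
local extremum of the (inverted, for decreases) single-trial SDF after
that trial's onset — requiring prominence ≥ 10% of the trial's dynamic
range to suppress noise peaks — marks the response peak.  Traces are
shifted so peaks align at the median peak time (preserving average
latency), averaged, and magnitude/FWHM extracted against the baseline
trend projection averaged over the trials' original onsets.  An optional
variant z-scores each trial by the across-trial mean and SD of per-trial
baseline firing rates before alignment; it refuses when baseline
variability is zero (noiseless inputs).

## Behavioral screening

RT = movement onset − go-cue; movement duration (MD) = target contact −
movement onset.  Error trials (wrong target, hold failure, timeout, or
RT beyond the state's response window: 1 s pre, 3 s post) are excluded
first.  Surviving trials are screened jointly on RT and MD: a trial is
an outlier when either metric deviates from the sample *mean* by more
than 6 MADs (MAD about the median).  This mean-centered rule is
implemented exactly as published; a conventional median-centered toggle
exists.  The mean-centered form has a known quirk — a sufficiently
extreme outlier drags the mean far enough to flag bulk trials too — that
the tests document.  Return movements longer than 6 s are labeled
experimenter-assisted.  Home-cage behavior enters as rater count tables
converted to events/min, with lateral bias = left − right rates and
rotation bias = clockwise − counterclockwise.

## Unit quality control

* Refractory screen: pass iff < 0.5% of ISIs are shorter than 1.5 ms.
* Rate gate: per state, units must fall within median ± 1.5·MAD of the
  population firing rate.
* Waveform screen: median waveforms reduce to three shape features
  (half-width of the dominant deflection at half-extremum; peak−trough
  magnitude difference normalized by their sum; pre/after-
  hyperpolarization difference normalized by their sum).  Features are
  standardized per dimension by their MAD and clustered with DBSCAN;
  noise points are discarded.  The clustering radius is not published,
  so it was calibrated on the planted-outlier fixture: with MAD
  standardization the inlier cloud has unit robust scale per dimension,
  inlier 4th-neighbor distances reach ≈3.3, and planted outliers sit at
  ≥ 50; the default is eps = 4.0 with min_neighbors = 4 (both in
  config).

## Population statistics

Chi-square tests are followed by adjusted (Haberman) standardized
residuals, (O−E)/√(E(1−row/N)(1−col/N)), flagged per cell at a
Bonferroni-corrected two-sided normal quantile.  Modality of a
distribution is selected by the smallest BIC among Gaussian mixtures
with 1–4 components (multiple seeded restarts).  Factorial ANOVA with
Tukey post-hocs, rank-sum and Kolmogorov–Smirnov comparisons are thin
wrappers over statsmodels/scipy — standard procedures, included so the
pipeline runs end to end.

## Synthetic sessions

The generator draws SPHPs uniform on 2–10 s, RT and MD from truncated
normals (re-drawn, not clipped, to preserve unimodality), and balanced
pseudo-random targets.  Regime defaults: pre RT 0.35 ± 0.05 s within a
1-s response window, baseline 69 sp/s; post RT 1.2 ± 0.4 s within 3 s,
baseline 26.5 sp/s.  The RT/MD distributional family is a modeling
choice (the task source constrains only the windows); MD defaults
(0.40 ± 0.08 s pre, 1.0 ± 0.3 s post) follow the same slowing pattern.
A per-trial response onset is placed at
go_cue + offset + λ·RT + N(0, jitter²); λ ∈ [0,1] interpolates from
pure cue locking to pure movement locking, so recovered ELI should equal
2λ − 1.  The firing rate is baseline + within-SPHP ramp + sinusoidal
modulation + Gaussian response phases (polyphasic: opposite-sign second
phase delayed 2.5σ_r, keeping half-max regions disjoint) + burst epochs
(multiplicative gain), rectified at 0; the ground truth stores the
realizable (rectified) first-phase amplitude for magnitude-recovery
tests.  Spikes arise by thinning an inhomogeneous Poisson process at
1-ms resolution (per-bin Bernoulli, at most one spike per bin — matching
the 1-kHz stamp model and keeping count statistics exact for the rate
oracles).  An optional dead time (default off) imposes a refractory
period for QC-path realism at the cost of a small rate bias, so rate-
recovery tests run with it off.  A companion helper renders *noiseless*
single-trial SDFs (the exact rate function through the SDF kernel),
used to test onset detection and event locking free of spiking noise.

What the generator does **not** emulate: non-Poisson ISI statistics
(renewal/gamma firing), rate co-fluctuations across trials, recording
nonstationarities, spike-sorting contamination, or correlated units.
Passing recovery tests therefore demonstrates correctness of the
estimators under the generative model, not robustness to every feature
of real recordings.

## Problem sizes and numerical choices

Simulation suites use desk-scale sizes chosen to keep each suite in the
tens of seconds while leaving comfortable statistical margins: 200 null
units for the omnibus false-positive bound, 100 Poisson units for null
burstiness, 30–60 replicates for ramp type-I and dispersion oracles,
40–100 trials per synthetic unit.  Recovery tolerances mirror the
closed-form oracles (10% on magnitudes, 15% on FWHM and IQR oracles,
±2 ms on noiseless step onsets, 0.05 on ELI).  Degenerate inputs are
handled explicitly: zero MAD flags nothing; constant traces yield
undetected onsets; all-equal rate populations gate only exact-median
units; zero baseline variability refuses z-scoring.
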