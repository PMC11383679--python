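"""Trial-by-trial response timing.

The response onset on each trial is found by sliding a 200-ms step
kernel (100 points at the single-trial SDF minimum followed by 100 at
its maximum, both taken over the go-cue-to-movement-end search span)
across the single-trial SDF at 1-ms steps; the best least-squares
position marks the onset.  Decrease-led responses are inverted first.

Event locking regresses the cue-to-response interval and the
response-to-movement interval against the behavioral RT over the same
trials.  Because the two intervals sum to the RT, the two slopes sum to
one, and the event-locking index

    ELI = (slope_cue_resp - slope_resp_mvt) / (slope_cue_resp + slope_resp_mvt)

runs from -1 (perfect cue locking) through 0 (timing covaries with the
RT midpoint) to +1 (perfect movement locking).

De-jittering realigns single-trial SDFs on their own response peaks
before averaging, recovering response magnitude and duration free of
trial-to-trial timing jitter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as spsig
from scipy import stats as sps

from .config import AnalysisConfig
from .responses import BaselineTrend
from .sdf import SDFTrace
from .session import TrialEvents

_DECREASE_LED = ("decr", "poly_di")


@dataclass
class TrialOnset:
    trial_index: int
    onset: Optional[float]           # s, session clock
    onset_rel_cue: Optional[float]   # ms
    onset_rel_move: Optional[float]  # ms
    fit_sse: Optional[float]
    peak_time: Optional[float] = None  # s, set by de-jittering
    detected: bool = False
    at_boundary: bool = False


@dataclass
class LockingResult:
    slope_cue_resp: float
    slope_resp_mvt: float
    p_cue_resp: float
    p_resp_mvt: float
    category: str       # cue_locked | move_locked | intermediate | indeterminate
    eli: float
    residual_iqr: Optional[float]
    n_trials_used: int


@dataclass
class DejitteredResponse:
    aligned_mean: SDFTrace
    magnitude: float
    fwhm: float
    fwhm_truncated: bool
    n_trials: int
    zscored_magnitude: Optional[float] = None
    zscored_fwhm: Optional[float] = None


# ---------------------------------------------------------------------------


def single_trial_onset(trace: SDFTrace, trial: TrialEvents, rtype: str,
                       config: Optional[AnalysisConfig] = None,
                       n_spikes_in_span: Optional[int] = None) -> TrialOnset:
    """Best-fit step-kernel position for one trial.

    ``trace`` is the single-trial SDF aligned on movement onset.  The
    kernel may overhang the search-span edges by up to half its length;
    the SDF is extended there by its edge values.  Ties break earliest.
    """
    config = config or AnalysisConfig()
    half = int(round(config.step_kernel_length * 1000)) // 2
    s0 = int(round(1000.0 * (trial.go_cue - trial.movement_onset)))
    s1 = int(round(1000.0 * (trial.movement_offset - trial.movement_onset)))
    undetected = TrialOnset(trial_index=trial.trial_index, onset=None,
                            onset_rel_cue=None, onset_rel_move=None,
                            fit_sse=None, detected=False)
    if n_spikes_in_span is not None and n_spikes_in_span < 2:
        return undetected

    g0 = int(trace.time_grid[0])
    g1 = int(trace.time_grid[-1]) + 1
    lo_t, hi_t = max(s0, g0), min(s1 + 1, g1)
    if hi_t - lo_t < 2:
        return undetected
    span = trace.values[lo_t - g0:hi_t - g0]
    if rtype in _DECREASE_LED:
        span = -span
    lo_v, hi_v = float(span.min()), float(span.max())
    if hi_v - lo_v <= 0:
        return undetected

    # pad by edge values so the kernel can overhang the span by `half`
    x = np.concatenate([np.full(half, span[0]), span, np.full(half, span[-1])])
    # SSE(t) over transitions t = lo_t .. hi_t-1; in padded coords the
    # transition sits at index k = (t - lo_t) + half
    c_lo = np.concatenate([[0.0], np.cumsum((x - lo_v) ** 2)])
    c_hi = np.concatenate([[0.0], np.cumsum((x - hi_v) ** 2)])
    ks = np.arange(hi_t - lo_t) + half
    sse = (c_lo[ks] - c_lo[ks - half]) + (c_hi[ks + half] - c_hi[ks])
    best = int(np.argmin(sse))       # argmin returns the earliest tie
    onset_rel_move = float(lo_t + best)
    onset_abs = trial.movement_onset + onset_rel_move / 1000.0
    return TrialOnset(
        trial_index=trial.trial_index, onset=onset_abs,
        onset_rel_cue=onset_rel_move - 1000.0 * (trial.go_cue
                                                 - trial.movement_onset),
        onset_rel_move=onset_rel_move, fit_sse=float(sse[best]),
        detected=True,
        at_boundary=best == 0 or best == len(sse) - 1)


# ---------------------------------------------------------------------------


def _regress(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Slope and two-sided p; constant y gives (0, 1), perfect fits p=0."""
    if np.allclose(y, y[0]):
        return 0.0, 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        fit = sps.linregress(x, y)
    p = fit.pvalue
    if not np.isfinite(p):
        resid = y - (fit.slope * x + fit.intercept)
        p = 0.0 if np.allclose(resid, 0) else 1.0
    return float(fit.slope), float(p)


def event_locking(onsets: Sequence[TrialOnset],
                  trials: Sequence[TrialEvents],
                  config: Optional[AnalysisConfig] = None) -> LockingResult:
    """Latency regressions, locking category, ELI and residual IQR.

    Both regressions use the identical set of trials (detected onset and
    valid RT), so slope_cue_resp + slope_resp_mvt = 1 holds exactly.
    """
    config = config or AnalysisConfig()
    by_index = {t.trial_index: t for t in trials}
    xs, y_cue, y_mvt = [], [], []
    for o in onsets:
        if not o.detected:
            continue
        t = by_index.get(o.trial_index)
        if t is None or t.movement_onset is None:
            continue
        rt = t.movement_onset - t.go_cue
        xs.append(rt)
        y_cue.append(o.onset - t.go_cue)
        y_mvt.append(t.movement_onset - o.onset)
    if len(xs) < 5:
        raise ValueError("need at least 5 detected onsets with valid RTs")
    x = np.array(xs)
    b_cue, p_cue = _regress(x, np.array(y_cue))
    b_mvt, p_mvt = _regress(x, np.array(y_mvt))

    alpha = config.secondary_alpha
    sig_cue = p_cue < alpha and b_cue > 0
    sig_mvt = p_mvt < alpha and b_mvt > 0
    if sig_mvt and not sig_cue:
        category = "cue_locked"
    elif sig_cue and not sig_mvt:
        category = "move_locked"
    elif sig_cue and sig_mvt:
        category = "intermediate"
    else:
        category = "indeterminate"
    eli = (b_cue - b_mvt) / (b_cue + b_mvt)

    resid_iqr = timing_dispersion(onsets, trials) if len(xs) >= 5 else None
    return LockingResult(slope_cue_resp=b_cue, slope_resp_mvt=b_mvt,
                         p_cue_resp=p_cue, p_resp_mvt=p_mvt,
                         category=category, eli=float(eli),
                         residual_iqr=resid_iqr, n_trials_used=len(xs))


def timing_dispersion(onsets: Sequence[TrialOnset],
                      trials: Sequence[TrialEvents]) -> float:
    """IQR (ms) of residual onset timing after regressing cue-referenced
    latency on RT.  (Residuals are identical for movement-referenced
    latency since RT is the regressor.)"""
    by_index = {t.trial_index: t for t in trials}
    xs, ys = [], []
    for o in onsets:
        if not o.detected:
            continue
        t = by_index.get(o.trial_index)
        if t is None or t.movement_onset is None:
            continue
        xs.append(t.movement_onset - t.go_cue)
        ys.append(o.onset_rel_cue)
    if len(xs) < 5:
        raise ValueError("need at least 5 detected onsets")
    x, y = np.array(xs), np.array(ys, dtype=float)
    slope, icpt = np.polyfit(x, y, 1)
    resid = y - (slope * x + icpt)
    q75, q25 = np.percentile(resid, [75, 25])
    return float(q75 - q25)


# ---------------------------------------------------------------------------
# de-jittering


def _half_width(dev: np.ndarray, peak_idx: int,
                magnitude: float) -> Tuple[float, bool]:
    half = abs(magnitude) / 2.0
    above = (np.abs(dev) >= half) & (np.sign(dev) == np.sign(magnitude))
    left = peak_idx
    while left > 0 and above[left - 1]:
        left -= 1
    right = peak_idx
    while right < dev.size - 1 and above[right + 1]:
        right += 1
    truncated = (left == 0 and above[0]) or \
                (right == dev.size - 1 and above[-1])
    return float(right - left + 1), truncated


def dejitter(traces: Sequence[SDFTrace], onsets: Sequence[TrialOnset],
             trials: Sequence[TrialEvents], rtype: str,
             trend: BaselineTrend,
             config: Optional[AnalysisConfig] = None,
             zscore: bool = False) -> DejitteredResponse:
    """Response-aligned mean SDF and de-jittered response metrics.

    Per trial the earliest sufficiently prominent rate extremum after
    that trial's detected onset marks the response peak; traces are
    shifted so peaks align at the median peak time, averaged, and the
    magnitude/FWHM extracted against the baseline-trend value averaged
    over the trials' original onsets.  Monophasic response types only.
    """
    config = config or AnalysisConfig()
    if rtype not in ("incr", "decr"):
        raise ValueError("de-jittering applies to monophasic responses only")
    invert = rtype == "decr"
    by_index = {t.trial_index: t for t in trials}

    peak_ms: List[int] = []
    used_traces: List[SDFTrace] = []
    used_onsets: List[TrialOnset] = []
    g0 = int(traces[0].time_grid[0])
    for trace, o in zip(traces, onsets):
        if not o.detected:
            continue
        t = by_index[o.trial_index]
        s1 = int(round(1000.0 * (t.movement_offset - t.movement_onset)))
        x = -trace.values if invert else trace.values
        lo = int(o.onset_rel_move) - g0
        hi = min(s1 - g0 + 1, x.size)
        if hi - lo < 3:
            continue
        seg = x[lo:hi]
        prom = config.peak_prominence_frac * (seg.max() - seg.min())
        peaks, _ = spsig.find_peaks(seg, prominence=max(prom, 1e-12))
        if peaks.size == 0:
            k = int(np.argmax(seg))   # monotone within span: take extremum
        else:
            k = int(peaks[0])
        peak_ms.append(lo + k + g0)
        used_traces.append(trace)
        used_onsets.append(o)
    if len(used_traces) < config.min_trials_per_direction:
        raise ValueError("fewer aligned trials than the per-direction "
                         "minimum")

    anchor = int(np.median(peak_ms))
    shifts = [p - anchor for p in peak_ms]
    n = used_traces[0].values.size
    max_s, min_s = max(shifts), min(shifts)
    lo_i, hi_i = max(0, -min_s), min(n, n - max_s)
    if hi_i - lo_i < 10:
        raise ValueError("insufficient overlap after realignment")

    stack = np.vstack([tr.values[lo_i + s:hi_i + s]
                       for tr, s in zip(used_traces, shifts)])
    base_level = float(np.mean([trend.project(o.onset_rel_move)
                                for o in used_onsets]))
    if zscore:
        b0 = trend.window_end_ms - int(config.baseline_window * 1000)
        b_rates = np.array([tr.window(b0, trend.window_end_ms).mean()
                            for tr in used_traces])
        mu, sd = float(b_rates.mean()), float(b_rates.std(ddof=1))
        if sd == 0:
            raise ValueError("zero baseline variability; cannot z-score")
        stack = (stack - mu) / sd
        base_level = (base_level - mu) / sd

    grid = np.arange(g0 + lo_i, g0 + hi_i)
    mean_vals = stack.mean(axis=0)
    dev = mean_vals - base_level
    peak_idx = int(np.argmin(dev)) if invert else int(np.argmax(dev))
    magnitude = float(dev[peak_idx])
    fwhm, truncated = _half_width(dev, peak_idx, magnitude)

    aligned = SDFTrace(align_event="response_peak", time_grid=grid,
                       values=mean_vals, n_trials=stack.shape[0],
                       flavor="mean",
                       per_point_sd=stack.std(axis=0, ddof=1))
    out = DejitteredResponse(aligned_mean=aligned, magnitude=magnitude,
                             fwhm=fwhm, fwhm_truncated=truncated,
                             n_trials=stack.shape[0])
    if zscore:
        out.zscored_magnitude = magnitude
        out.zscored_fwhm = fwhm
    return out
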