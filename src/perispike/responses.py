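"""Perimovement response detection, classification and quantification.

Single-trial SDFs aligned on movement onset are averaged per reach
direction.  A response is a run of at least 60 consecutive milliseconds
within the test window (median go-cue time to median movement-offset
time across trials) where the across-trial firing rate differs from a
trend-corrected baseline at omnibus p < 0.001 with Bonferroni
correction over tested points.  Responses are classified by the sign of
the earliest significant run (increase, decrease, or polyphasic +/- and
-/+), and quantified by onset latency, signed magnitude relative to the
projected baseline trend, and full width at half-maximum change (FWHM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .config import AnalysisConfig
from .sdf import SDFTrace, compute_sdf, mean_sdf
from .session import SessionRecord, TrialEvents, UnitSpikeTrain


@dataclass
class BaselineTrend:
    slope: float          # sp/s per s
    intercept: float      # sp/s at the window end (= test-window start)
    sd: float             # sp/s, residual SD about the line
    window_end_ms: int    # grid time where the window ends

    def project(self, t_ms) -> np.ndarray:
        """Trend value extrapolated to grid time(s) t_ms."""
        t = np.asarray(t_ms, dtype=float)
        return self.intercept + self.slope * (t - self.window_end_ms) / 1000.0


@dataclass
class ResponseSegment:
    start: int   # ms relative to align event
    end: int     # exclusive
    sign: int    # +1 or -1


@dataclass
class ResponseProfile:
    unit_id: str
    direction: str
    rtype: str                       # incr | decr | poly_id | poly_di | none
    segments: List[ResponseSegment] = field(default_factory=list)
    onset_latency_move: Optional[float] = None   # ms
    onset_latency_cue: Optional[float] = None    # ms
    magnitude: Optional[float] = None            # sp/s, signed, initial phase
    fwhm: Optional[float] = None                 # ms, initial phase
    fwhm_truncated: bool = False
    directional_300ms: Optional[bool] = None
    directional_whole: Optional[bool] = None
    test_window: Optional[Tuple[int, int]] = None
    trend: Optional[BaselineTrend] = None


# ---------------------------------------------------------------------------


def fit_baseline(mean_trace: SDFTrace, test_window_start: int,
                 config: Optional[AnalysisConfig] = None) -> BaselineTrend:
    """OLS of the mean SDF on time over the 700-ms window ending at the
    test-window start; the residual SD summarizes baseline variability."""
    config = config or AnalysisConfig()
    w = int(round(config.baseline_window * 1000))
    t0 = test_window_start - w
    y = mean_trace.window(t0, test_window_start)
    t = np.arange(t0, test_window_start, dtype=float) / 1000.0
    if y.size < 2:
        raise ValueError("baseline window outside trace")
    slope, icpt = np.polyfit(t, y, 1)
    resid = y - (slope * t + icpt)
    return BaselineTrend(slope=float(slope),
                         intercept=float(slope * test_window_start / 1000.0
                                         + icpt),
                         sd=float(resid.std(ddof=0)),
                         window_end_ms=test_window_start)


def _per_point_p(stack: np.ndarray, target: np.ndarray,
                 trend_sd: float, method: str) -> np.ndarray:
    """Two-sided p-value per column for the across-trial values against
    the trend projection."""
    n = stack.shape[0]
    m = stack.mean(axis=0)
    if method == "zscore":
        if trend_sd == 0:
            return np.where(m == target, 1.0, 0.0)
        z = (m - target) / trend_sd
        return 2 * sps.norm.sf(np.abs(z))
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m - target) / (sd / np.sqrt(n))
        p = 2 * sps.t.sf(np.abs(t), df=n - 1)
    p = np.where(sd == 0, np.where(m == target, 1.0, 0.0), p)
    return p


def detect_response(trial_traces: Sequence[SDFTrace],
                    trials: Sequence[TrialEvents],
                    config: Optional[AnalysisConfig] = None,
                    unit_id: str = "", direction: str = "") -> ResponseProfile:
    """Detect and classify the perimovement response of one unit x direction.

    ``trial_traces`` are single-trial SDFs aligned on movement onset (one
    per valid trial, matching ``trials``); they must cover the baseline
    window plus the test window.
    """
    config = config or AnalysisConfig()
    if len(trial_traces) != len(trials):
        raise ValueError("one trace per trial required")
    rel_cue = [1000.0 * (t.go_cue - t.movement_onset) for t in trials]
    rel_off = [1000.0 * (t.movement_offset - t.movement_onset) for t in trials]
    t_start = int(round(np.median(rel_cue)))
    t_end = int(round(np.median(rel_off)))
    n_points = t_end - t_start
    if n_points < config.min_response_duration * 1000:
        raise ValueError("test window shorter than the minimum response "
                         "duration")

    mtrace = mean_sdf(list(trial_traces))
    trend = fit_baseline(mtrace, t_start, config)
    stack = np.vstack([tr.window(t_start, t_end) for tr in trial_traces])
    times = np.arange(t_start, t_end)
    target = trend.project(times)
    p = _per_point_p(stack, target, trend.sd, config.per_point_test)

    alpha = config.omnibus_alpha_response / n_points
    sig = p < alpha
    delta = stack.mean(axis=0) - target
    signs = np.where(delta >= 0, 1, -1)

    min_run = int(round(config.min_response_duration * 1000))
    segments: List[ResponseSegment] = []
    i = 0
    while i < n_points:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j < n_points and sig[j] and signs[j] == signs[i]:
            j += 1
        if j - i >= min_run:
            segments.append(ResponseSegment(start=int(times[i]),
                                            end=int(times[j - 1]) + 1,
                                            sign=int(signs[i])))
        i = j

    if not segments:
        rtype = "none"
    else:
        first_sign = segments[0].sign
        signs_present = {s.sign for s in segments}
        if len(signs_present) == 1:
            rtype = "incr" if first_sign > 0 else "decr"
        else:
            rtype = "poly_id" if first_sign > 0 else "poly_di"

    profile = ResponseProfile(unit_id=unit_id, direction=direction,
                              rtype=rtype, segments=segments,
                              test_window=(t_start, t_end), trend=trend)
    if segments:
        profile.onset_latency_move = float(segments[0].start)
        profile = response_metrics(mtrace, trend, profile, config)
    return profile


def response_metrics(mean_trace: SDFTrace, trend: BaselineTrend,
                     profile: ResponseProfile,
                     config: Optional[AnalysisConfig] = None
                     ) -> ResponseProfile:
    """Magnitude and FWHM of the initial response phase.

    Magnitude is the signed extremum of (mean SDF - projected trend)
    within the initial segment; FWHM is the width of the contiguous
    region around the extremum where the deviation stays at or above
    half the magnitude, truncated (and flagged) at the trace edges.
    """
    config = config or AnalysisConfig()
    if not profile.segments:
        raise ValueError("profile has no segments")
    seg = profile.segments[0]
    dev_all = mean_trace.values - trend.project(mean_trace.time_grid)
    g0 = int(mean_trace.time_grid[0])
    i0, i1 = seg.start - g0, seg.end - g0
    seg_dev = dev_all[i0:i1]
    if seg.sign > 0:
        k = int(np.argmax(seg_dev))
    else:
        k = int(np.argmin(seg_dev))
    magnitude = float(seg_dev[k])
    peak_idx = i0 + k

    half = abs(magnitude) / 2.0
    above = np.abs(dev_all) >= half
    # same-sign constraint so the FWHM region does not leak across phases
    above &= (np.sign(dev_all) == np.sign(magnitude))
    left = peak_idx
    while left > 0 and above[left - 1]:
        left -= 1
    right = peak_idx
    while right < dev_all.size - 1 and above[right + 1]:
        right += 1
    truncated = (left == 0 and above[0]) or \
                (right == dev_all.size - 1 and above[-1])
    profile.magnitude = magnitude
    profile.fwhm = float(right - left + 1)
    profile.fwhm_truncated = bool(truncated)
    return profile


# ---------------------------------------------------------------------------
# convenience drivers


def trial_traces_for_direction(session: SessionRecord, unit: UnitSpikeTrain,
                               direction: str,
                               valid_trials: Sequence[TrialEvents],
                               config: Optional[AnalysisConfig] = None,
                               pad_ms: int = 200
                               ) -> Tuple[List[TrialEvents], List[SDFTrace]]:
    """Movement-onset-aligned single-trial SDFs for one direction, on a
    window covering baseline + test windows for these trials."""
    config = config or AnalysisConfig()
    trials = [t for t in valid_trials if t.target == direction
              and t.movement_onset is not None
              and t.movement_offset is not None]
    if not trials:
        return [], []
    rel_cue = [1000.0 * (t.go_cue - t.movement_onset) for t in trials]
    rel_off = [1000.0 * (t.movement_offset - t.movement_onset) for t in trials]
    w0 = int(round(np.median(rel_cue))) - int(config.baseline_window * 1000) \
        - pad_ms
    w1 = int(round(np.median(rel_off))) + pad_ms
    traces = [compute_sdf(unit.spike_times, t.movement_onset, (w0, w1), config)
              for t in trials]
    return trials, traces


def analyze_direction(session: SessionRecord, unit: UnitSpikeTrain,
                      direction: str, valid_trials: Sequence[TrialEvents],
                      config: Optional[AnalysisConfig] = None
                      ) -> Optional[ResponseProfile]:
    """Detect the response for one direction; None when the direction has
    fewer than the minimum number of valid trials."""
    config = config or AnalysisConfig()
    trials, traces = trial_traces_for_direction(session, unit, direction,
                                                valid_trials, config)
    if len(trials) < config.min_trials_per_direction:
        return None
    return detect_response(traces, trials, config, unit_id=unit.unit_id,
                           direction=direction)


def cue_aligned_latency(session: SessionRecord, unit: UnitSpikeTrain,
                        profile: ResponseProfile,
                        valid_trials: Sequence[TrialEvents],
                        config: Optional[AnalysisConfig] = None
                        ) -> Optional[float]:
    """Re-run detection aligned on the go-cue and return the onset latency
    (ms relative to the cue) of the same-direction response."""
    config = config or AnalysisConfig()
    trials = [t for t in valid_trials if t.target == profile.direction
              and t.movement_onset is not None
              and t.movement_offset is not None]
    if len(trials) < config.min_trials_per_direction:
        return None
    rel_off = [1000.0 * (t.movement_offset - t.go_cue) for t in trials]
    w0 = -int(config.baseline_window * 1000) - 200
    w1 = int(round(np.median(rel_off))) + 200
    traces = [compute_sdf(unit.spike_times, t.go_cue, (w0, w1), config,
                          align_event="go_cue") for t in trials]
    mtrace = mean_sdf(traces)
    trend = fit_baseline(mtrace, 0, config)
    t_end = int(round(np.median(rel_off)))
    stack = np.vstack([tr.window(0, t_end) for tr in traces])
    times = np.arange(0, t_end)
    target = trend.project(times)
    p = _per_point_p(stack, target, trend.sd, config.per_point_test)
    sig = p < config.omnibus_alpha_response / t_end
    delta = stack.mean(axis=0) - target
    signs = np.where(delta >= 0, 1, -1)
    min_run = int(round(config.min_response_duration * 1000))
    i = 0
    while i < t_end:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j < t_end and sig[j] and signs[j] == signs[i]:
            j += 1
        if j - i >= min_run:
            return float(times[i])
        i = j
    return None


def test_directionality(unit: UnitSpikeTrain,
                        profiles: Dict[str, Optional[ResponseProfile]],
                        trials_by_direction: Dict[str, Sequence[TrialEvents]],
                        config: Optional[AnalysisConfig] = None
                        ) -> Tuple[Optional[bool], bool]:
    """Rank-sum tests of left vs right per-trial spike counts.

    First window: 300 ms from the unit's earliest detected response onset
    (relative to movement onset); undefined when no response was detected.
    Second window: go-cue to movement offset of each trial.
    """
    config = config or AnalysisConfig()
    st = np.asarray(unit.spike_times)
    for d in ("left", "right"):
        if len(trials_by_direction.get(d, [])) < config.min_trials_per_direction:
            raise ValueError(f"fewer than {config.min_trials_per_direction} "
                             f"trials for direction {d!r}")

    onsets = [p.onset_latency_move for p in profiles.values()
              if p is not None and p.onset_latency_move is not None]
    directional_300: Optional[bool] = None
    if onsets:
        t_on = min(onsets) / 1000.0
        counts = {}
        for d, trs in trials_by_direction.items():
            counts[d] = [np.sum((st >= t.movement_onset + t_on)
                                & (st < t.movement_onset + t_on
                                   + config.directionality_window))
                         for t in trs]
        _, p300 = sps.ranksums(counts["left"], counts["right"])
        directional_300 = bool(p300 < config.secondary_alpha)

    counts_whole = {}
    for d, trs in trials_by_direction.items():
        counts_whole[d] = [np.sum((st >= t.go_cue) & (st < t.movement_offset))
                           for t in trs]
    _, pw = sps.ranksums(counts_whole["left"], counts_whole["right"])
    return directional_300, bool(pw < config.secondary_alpha)
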