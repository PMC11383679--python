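"""Per-trial behavioral metrics, exclusion rules, and home-cage summaries.

RT is the go-cue-to-movement-onset interval and MD the movement-onset-
to-target-contact interval.  Error trials (wrong target, timeout, hold
failure, or RT beyond the state's response window) are excluded, and
surviving trials are screened with a MAD-based outlier rule: a trial is
an outlier when either metric deviates from the sample *mean* by more
than 6 median absolute deviations (the rule is applied exactly as
published; a conventional median-centered variant is available via
``AnalysisConfig.outlier_center``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .config import AnalysisConfig
from .session import TrialEvents
from .stats import mad


@dataclass
class BehavioralMetrics:
    trial_index: int
    rt: Optional[float]
    md: Optional[float]
    return_duration: Optional[float]
    valid: bool
    exclusion_reason: str      # none | error_trial | rt_outlier | md_outlier
    assisted_return: bool


@dataclass
class HomeCageSummary:
    """Event rates (events/min) by behavior and side, with lateral biases."""

    rates: Dict[str, float]
    lateral_bias: float        # grooming left - right
    rotation_bias: float       # clockwise - counterclockwise


def compute_trial_metrics(trial: TrialEvents, config: AnalysisConfig,
                          state: str) -> BehavioralMetrics:
    """RT/MD for one trial plus error-trial and assisted-return flags."""
    if state not in config.response_windows:
        raise ValueError(f"unknown state {state!r}")
    window = config.response_windows[state]

    rt = md = None
    if trial.movement_onset is not None:
        rt = trial.movement_onset - trial.go_cue
        if trial.movement_offset is not None:
            md = trial.movement_offset - trial.movement_onset
    elif trial.outcome == "correct":
        raise ValueError(
            f"trial {trial.trial_index}: correct-coded trial lacks "
            "movement events")

    return_duration = None
    if trial.return_complete is not None and trial.reward is not None:
        return_duration = trial.return_complete - trial.reward
    assisted = (return_duration is not None
                and return_duration > config.assisted_return_threshold)

    valid = trial.outcome == "correct" and rt is not None and rt <= window
    reason = "none" if valid else "error_trial"
    return BehavioralMetrics(trial_index=trial.trial_index, rt=rt, md=md,
                             return_duration=return_duration, valid=valid,
                             exclusion_reason=reason, assisted_return=assisted)


def flag_outlier_trials(values: Sequence[float], k: float = 6.0,
                        center: str = "mean") -> np.ndarray:
    """Flag values deviating from the center by more than ``k`` MADs.

    MAD is always taken about the median; the deviation is measured from
    the mean by default (as published) or from the median.  A zero MAD
    flags nothing.
    """
    v = np.asarray(values, dtype=float)
    if np.sum(np.isfinite(v)) < 3:
        raise ValueError("need at least 3 finite values")
    m = mad(v[np.isfinite(v)])
    if m == 0:
        return np.zeros(v.shape, dtype=bool)
    c = np.nanmean(v) if center == "mean" else np.nanmedian(v)
    with np.errstate(invalid="ignore"):
        return np.abs(v - c) > k * m


def screen_trials(trials: Sequence[TrialEvents], config: AnalysisConfig,
                  state: str) -> List[BehavioralMetrics]:
    """Full exclusion cascade: error trials, then joint RT/MD outlier flags.

    A trial is excluded if flagged on either metric; the outlier statistics
    are computed over non-error trials only.
    """
    metrics = [compute_trial_metrics(t, config, state) for t in trials]
    ok = [m for m in metrics if m.valid]
    if len(ok) >= 3:
        rts = [m.rt for m in ok]
        mds = [m.md if m.md is not None else np.nan for m in ok]
        rt_bad = flag_outlier_trials(rts, config.trial_outlier_k,
                                     config.outlier_center)
        md_bad = flag_outlier_trials(mds, config.trial_outlier_k,
                                     config.outlier_center)
        for m, rb, mb in zip(ok, rt_bad, md_bad):
            if rb:
                m.valid, m.exclusion_reason = False, "rt_outlier"
            elif mb:
                m.valid, m.exclusion_reason = False, "md_outlier"
    return metrics


def summarize_home_cage(counts: Dict[str, Sequence[float]],
                        durations: Sequence[float]) -> HomeCageSummary:
    """Convert per-segment event counts into rates and lateral biases.

    ``counts`` maps category names (``groom_left``, ``groom_right``,
    ``rotate_cw``, ``rotate_ccw``) to per-segment counts; ``durations``
    holds segment lengths in minutes.
    """
    dur = np.asarray(durations, dtype=float)
    if np.any(dur <= 0):
        raise ValueError("segment durations must be positive")
    total = dur.sum()
    rates = {}
    for key, c in counts.items():
        c = np.asarray(c, dtype=float)
        if np.any(c < 0):
            raise ValueError(f"negative counts in {key!r}")
        if c.shape != dur.shape:
            raise ValueError(f"counts/durations mismatch for {key!r}")
        rates[key] = float(c.sum() / total)
    lateral = rates.get("groom_left", 0.0) - rates.get("groom_right", 0.0)
    rotation = rates.get("rotate_cw", 0.0) - rates.get("rotate_ccw", 0.0)
    return HomeCageSummary(rates=rates, lateral_bias=lateral,
                           rotation_bias=rotation)
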