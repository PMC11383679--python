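"""Synthetic session generator with known ground truth.

Emulates the statistical structure of a choice reaction-time reaching
session recorded from a basal-ganglia output neuron: a uniform 2-10 s
start-position hold period (SPHP) precedes each go-cue, reaction time
(RT) and movement duration (MD) are truncated-normal, and the unit fires
as an inhomogeneous Poisson process whose rate combines a baseline, an
optional within-SPHP ramp, an optional sinusoidal (e.g. beta-band) rate
modulation, burst epochs, and a perimovement response of controllable
shape, amplitude, latency and trial-to-trial jitter.

The locking parameter ``lock_lambda`` places the response onset at

    onset = go_cue + onset_offset + lambda * RT + N(0, jitter_sd),

so lambda = 0 yields perfect cue-locking, lambda = 1 perfect
movement-locking, and the recovered event-locking index should equal
2*lambda - 1.

Two behavioral regimes are provided: ``pre`` (fast; RT 0.35 +- 0.05 s
within a 1-s response window, baseline 69 sp/s) and ``post``
(parkinsonian; RT 1.2 +- 0.4 s within a 3-s window, baseline 26.5 sp/s),
matching the population means of the study conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .sdf import SDFTrace, gaussian_kernel
from .session import SessionRecord, TrialEvents, UnitSpikeTrain

RESPONSE_TYPES = ("incr", "decr", "poly_id", "poly_di", "none")

_REGIME_DEFAULTS = {
    "pre": dict(rt_mean=0.35, rt_sd=0.05, md_mean=0.40, md_sd=0.08,
                baseline_rate=69.0, response_window=1.0,
                target_hold=(0.5, 1.0), return_range=(0.8, 1.5)),
    "post": dict(rt_mean=1.2, rt_sd=0.4, md_mean=1.0, md_sd=0.3,
                 baseline_rate=26.5, response_window=3.0,
                 target_hold=(0.1, 0.1), return_range=(6.5, 9.0)),
}


@dataclass
class SynthConfig:
    """Full generative parameterization of one synthetic unit/session."""

    seed: int = 0
    regime: str = "pre"
    n_trials: int = 60
    sphp_range: Tuple[float, float] = (2.0, 10.0)
    rt_mean: Optional[float] = None      # None -> regime default
    rt_sd: Optional[float] = None
    md_mean: Optional[float] = None
    md_sd: Optional[float] = None
    baseline_rate: Optional[float] = None  # sp/s
    ramp_slope: float = 0.0              # sp/s per s during SPHP
    osc_freq: float = 0.0                # Hz
    osc_depth: float = 0.0               # fraction of baseline
    burst_rate: float = 0.0              # bursts/min of SPHP time
    burst_gain: float = 4.0              # multiplicative rate factor
    burst_len: float = 0.200             # s
    response_type: str = "none"
    response_amp: float = 30.0           # sp/s, signed per phase by type
    response_sigma: float = 0.060        # s, Gaussian-bump SD per phase
    lock_lambda: float = 0.0             # 0 cue-locked .. 1 movement-locked
    onset_offset: float = 0.100          # s, constant latency after go-cue
    jitter_sd: float = 0.0               # s, trial-to-trial onset jitter
    direction_gain: Dict[str, float] = field(
        default_factory=lambda: {"left": 1.0, "right": 1.0})
    error_rate: float = 0.0
    refractory: float = 0.0   # s; dead time imposed after each spike
                              # (0 = pure Poisson, exact count statistics)

    def __post_init__(self) -> None:
        if self.regime not in _REGIME_DEFAULTS:
            raise ValueError(f"unknown regime {self.regime!r}")
        if not 0.0 <= self.lock_lambda <= 1.0:
            raise ValueError("lock_lambda must lie in [0, 1]")
        if self.response_type not in RESPONSE_TYPES:
            raise ValueError(f"unknown response_type {self.response_type!r}")
        d = _REGIME_DEFAULTS[self.regime]
        for name in ("rt_mean", "rt_sd", "md_mean", "md_sd", "baseline_rate"):
            if getattr(self, name) is None:
                setattr(self, name, d[name])
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")

    @property
    def response_window(self) -> float:
        return _REGIME_DEFAULTS[self.regime]["response_window"]

    def phases(self) -> List[Tuple[float, float]]:
        """(signed amplitude, onset delay in s) per response phase."""
        a, s = self.response_amp, self.response_sigma
        if self.response_type == "none":
            return []
        if self.response_type == "incr":
            return [(abs(a), 0.0)]
        if self.response_type == "decr":
            return [(-abs(a), 0.0)]
        # polyphasic: opposite-sign second phase 2.5 sigma later
        if self.response_type == "poly_id":
            return [(abs(a), 0.0), (-abs(a), 2.5 * s)]
        return [(-abs(a), 0.0), (abs(a), 2.5 * s)]


@dataclass
class GroundTruth:
    """Latent per-trial quantities behind a generated session."""

    config: SynthConfig
    trial_table: pd.DataFrame   # trial_index, target, valid, rt, md, onset
    phases: List[Tuple[float, float]]       # signed amp, delay (s)
    realized_amp: float                     # first-phase amp after rectification
    burst_epochs: List[Tuple[float, float]]
    warnings: List[str] = field(default_factory=list)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    """Re-draw (not clip) until the value falls in (lo, hi]."""
    if sd == 0:
        return float(np.clip(mean, lo + 1e-9, hi))
    for _ in range(10000):
        x = rng.normal(mean, sd)
        if lo < x <= hi:
            return float(x)
    raise RuntimeError("truncated normal draw failed")


def _draw_trials(config: SynthConfig, rng: np.random.Generator):
    d = _REGIME_DEFAULTS[config.regime]
    n = config.n_trials
    targets = np.array(["left"] * (n // 2) + ["right"] * (n - n // 2))
    rng.shuffle(targets)
    trials: List[TrialEvents] = []
    rows = []
    cursor = 5.0
    for i in range(n):
        sphp = rng.uniform(*config.sphp_range)
        sphp_start = cursor
        go_cue = sphp_start + sphp
        rt = _truncnorm(rng, config.rt_mean, config.rt_sd, 0.05,
                        config.response_window)
        md = _truncnorm(rng, config.md_mean, config.md_sd, 0.05, 10.0)
        is_error = rng.random() < config.error_rate
        outcome = "correct"
        onset_mv: Optional[float] = go_cue + rt
        offset_mv: Optional[float] = go_cue + rt + md
        reward: Optional[float] = None
        if is_error:
            outcome = "timeout" if rng.random() < 0.5 else "wrong_target"
            if outcome == "timeout":
                onset_mv = offset_mv = None
        hold = rng.uniform(*d["target_hold"])
        ret = rng.uniform(*d["return_range"])
        if offset_mv is not None and outcome == "correct":
            reward = offset_mv + hold
            return_complete = reward + ret
            cursor = return_complete + 0.5
        else:
            return_complete = None
            cursor = go_cue + config.response_window + 1.0
        trials.append(TrialEvents(
            trial_index=i, target=str(targets[i]), sphp_start=sphp_start,
            go_cue=go_cue, movement_onset=onset_mv, movement_offset=offset_mv,
            reward=reward, return_complete=return_complete, outcome=outcome))
        valid = outcome == "correct"
        resp_onset = (go_cue + config.onset_offset + config.lock_lambda * rt
                      + (rng.normal(0.0, config.jitter_sd)
                         if config.jitter_sd > 0 else 0.0)) if valid else np.nan
        rows.append(dict(trial_index=i, target=str(targets[i]), valid=valid,
                         rt=rt if valid else np.nan, md=md if valid else np.nan,
                         onset=resp_onset))
    return trials, pd.DataFrame(rows)


def rate_on_grid(config: SynthConfig, trials: Sequence[TrialEvents],
                 table: pd.DataFrame,
                 burst_epochs: Sequence[Tuple[float, float]],
                 t0: float, t1: float) -> np.ndarray:
    """Ground-truth firing rate (sp/s) on the 1-ms grid covering [t0, t1)."""
    n = int(round((t1 - t0) * 1000))
    t = t0 + (np.arange(n) + 0.5) / 1000.0
    r = np.full(n, float(config.baseline_rate))
    if config.osc_depth:
        r += config.baseline_rate * config.osc_depth * np.sin(
            2 * np.pi * config.osc_freq * t)
    if config.ramp_slope:
        for tr in trials:
            i0 = max(0, int(round((tr.sphp_start - t0) * 1000)))
            i1 = min(n, int(round((tr.go_cue - t0) * 1000)))
            if i1 > i0:
                r[i0:i1] += config.ramp_slope * (t[i0:i1] - tr.sphp_start)
    phases = config.phases()
    if phases:
        by_index = {tr.trial_index: tr for tr in trials}
        for row in table.itertuples():
            if not row.valid or not np.isfinite(row.onset):
                continue
            gain = config.direction_gain.get(by_index[row.trial_index].target,
                                             1.0)
            for amp, delay in phases:
                mu = row.onset + delay
                lo = max(0, int(round((mu - 5 * config.response_sigma - t0)
                                      * 1000)))
                hi = min(n, int(round((mu + 5 * config.response_sigma - t0)
                                      * 1000)))
                if hi > lo:
                    r[lo:hi] += amp * gain * np.exp(
                        -0.5 * ((t[lo:hi] - mu) / config.response_sigma) ** 2)
    for b0, b1 in burst_epochs:
        i0 = max(0, int(round((b0 - t0) * 1000)))
        i1 = min(n, int(round((b1 - t0) * 1000)))
        if i1 > i0:
            r[i0:i1] += config.baseline_rate * (config.burst_gain - 1.0)
    return np.maximum(r, 0.0)


def _draw_burst_epochs(config: SynthConfig, trials, rng):
    epochs = []
    if config.burst_rate <= 0:
        return epochs
    per_s = config.burst_rate / 60.0
    for tr in trials:
        dur = tr.go_cue - tr.sphp_start
        for _ in range(rng.poisson(per_s * dur)):
            b0 = rng.uniform(tr.sphp_start, tr.go_cue - config.burst_len)
            epochs.append((b0, b0 + config.burst_len))
    return sorted(epochs)


def generate_session(config: SynthConfig,
                     unit_id: str = "u0") -> Tuple[SessionRecord, GroundTruth]:
    """Draw one session and the latent ground truth behind it.

    Spikes are generated by thinning an inhomogeneous Poisson process at
    1-ms resolution (at most one spike per bin, matching the 1-kHz stamp
    resolution of the data model).
    """
    rng = np.random.default_rng(config.seed)
    trials, table = _draw_trials(config, rng)
    burst_epochs = _draw_burst_epochs(config, trials, rng)

    t0 = trials[0].sphp_start - 1.0
    t_end = max(x for tr in trials
                for x in (tr.go_cue + config.response_window + 1.0,
                          tr.return_complete or 0.0)) + 1.0
    rate = rate_on_grid(config, trials, table, burst_epochs, t0, t_end)
    hit = rng.random(rate.size) < rate / 1000.0
    idx = np.flatnonzero(hit)
    if config.refractory > 0 and idx.size:
        dead_bins = int(np.ceil(config.refractory * 1000))
        kept = [idx[0]]
        for i in idx[1:]:
            if i - kept[-1] >= dead_bins:
                kept.append(i)
        idx = np.array(kept)
    spikes = t0 + (idx + 0.5) / 1000.0

    warnings = []
    min_per_dir = 10
    n_valid = int(table["valid"].sum())
    if config.n_trials < 2 * min_per_dir:
        warnings.append("fewer trials than twice the per-direction minimum")

    phases = config.phases()
    realized = 0.0
    if phases:
        # a decrease cannot exceed the baseline after rectification
        amp0 = phases[0][0]
        realized = max(amp0, -config.baseline_rate) if amp0 < 0 else amp0

    session = SessionRecord(
        session_id=f"synth-{config.regime}-{config.seed}",
        subject_id="synth", state=config.regime, trials=trials,
        units=[UnitSpikeTrain(unit_id=unit_id, spike_times=spikes)])
    session.validate()
    gt = GroundTruth(config=config, trial_table=table, phases=phases,
                     realized_amp=realized, burst_epochs=burst_epochs,
                     warnings=warnings)
    _ = n_valid
    return session, gt


def generate_population(
        configs: Union[SynthConfig, Sequence[SynthConfig]],
        mixture: Dict[str, float],
        n_units: Optional[int] = None,
) -> List[Tuple[SessionRecord, GroundTruth]]:
    """Generate a population of units with response types drawn per mixture.

    ``configs`` may be a single template (replicated ``n_units`` times with
    derived seeds) or an explicit list; each unit's ``response_type`` is
    drawn from ``mixture`` (proportions must sum to 1).
    """
    if not mixture:
        raise ValueError("empty mixture")
    total = sum(mixture.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixture proportions sum to {total}, not 1")
    for k in mixture:
        if k not in RESPONSE_TYPES:
            raise ValueError(f"unknown response type {k!r} in mixture")

    if isinstance(configs, SynthConfig):
        if n_units is None:
            raise ValueError("n_units required with a single template config")
        base = configs
        configs = [replace(base, seed=base.seed + 1013 * (i + 1))
                   for i in range(n_units)]
    rng = np.random.default_rng(configs[0].seed + 7919)
    types = list(mixture.keys())
    probs = np.array([mixture[t] for t in types])
    out = []
    for i, cfg in enumerate(configs):
        rtype = types[int(rng.choice(len(types), p=probs))]
        cfg_i = replace(cfg, response_type=rtype)
        out.append(generate_session(cfg_i, unit_id=f"u{i:03d}"))
    return out


# ---------------------------------------------------------------------------
# noiseless traces (exact rate functions through the SDF kernel)


def noiseless_trial_sdfs(config: SynthConfig, window: Tuple[int, int],
                         analysis: Optional[AnalysisConfig] = None
                         ) -> Tuple[List[TrialEvents], List[SDFTrace],
                                    GroundTruth]:
    """Exact single-trial SDFs: the ground-truth rate function smoothed by
    the SDF kernel, with no Poisson sampling.

    Traces are aligned on movement onset over ``window`` (ms).  Useful for
    testing onset detection and event locking free of spiking noise.
    """
    analysis = analysis or AnalysisConfig()
    rng = np.random.default_rng(config.seed)
    trials, table = _draw_trials(config, rng)
    kernel = gaussian_kernel(analysis.sdf_sigma)
    radius = (kernel.size - 1) // 2
    w0, w1 = int(window[0]), int(window[1])
    traces = []
    valid_trials = []
    for tr in trials:
        if tr.outcome != "correct" or tr.movement_onset is None:
            continue
        a = tr.movement_onset
        lo = a + (w0 - radius) / 1000.0
        hi = a + (w1 + radius) / 1000.0
        r = rate_on_grid(config, trials, table, [], lo, hi)
        vals = np.convolve(r, kernel, mode="same")[radius:radius + (w1 - w0)]
        traces.append(SDFTrace(align_event="movement_onset",
                               time_grid=np.arange(w0, w1), values=vals,
                               n_trials=1))
        valid_trials.append(tr)
    gt = GroundTruth(config=config, trial_table=table, phases=config.phases(),
                     realized_amp=config.phases()[0][0] if config.phases()
                     else 0.0, burst_epochs=[])
    return valid_trials, traces, gt


# ---------------------------------------------------------------------------
# waveform fixtures


def _waveform_template(trough_sigma: float, pre_amp: float, post_amp: float,
                       n: int = 81, dt: float = 0.025) -> np.ndarray:
    """Triphasic extracellular-like template: pre-hyperpolarization bump,
    dominant trough, after-hyperpolarization bump.  Times in ms."""
    t = (np.arange(n) - n // 2) * dt
    w = (pre_amp * np.exp(-0.5 * ((t + 0.45) / 0.12) ** 2)
         - 1.0 * np.exp(-0.5 * (t / trough_sigma) ** 2)
         + post_amp * np.exp(-0.5 * ((t - 0.55) / 0.18) ** 2))
    return w


def generate_waveforms(n_inliers: int, n_outliers: int,
                       seed: int = 0) -> List[np.ndarray]:
    """Median-waveform fixtures: one tight feature-space cluster plus
    planted outliers displaced far beyond the clustering radius."""
    if n_inliers < 5:
        raise ValueError("need at least 5 inlier waveforms")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_inliers):
        out.append(_waveform_template(
            trough_sigma=rng.normal(0.12, 0.008),
            pre_amp=rng.normal(0.25, 0.015),
            post_amp=rng.normal(0.35, 0.015)))
    for _ in range(n_outliers):
        out.append(_waveform_template(
            trough_sigma=rng.normal(0.40, 0.01),
            pre_amp=rng.normal(0.85, 0.02),
            post_amp=rng.normal(0.10, 0.01)))
    return out
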