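"""Resting-state discharge characterization during start-position hold
periods (SPHPs): firing rate, ISI variability, Poisson-surprise bursts,
shuffle-normalized spectra, and linear rate ramps.

The SPHP is a 2-10 s pre-cue rest interval; all resting measures pool
across a session's SPHPs.  Burst detection follows the Legendy-Salcman
Poisson-surprise method (natural-log surprise, threshold 5, at least 4
spikes).  Oscillation detection computes a Hann-tapered periodogram over
non-overlapping 512-ms segments, normalizes it by the mean spectrum of
ISI-order-shuffled surrogates (which removes refractory-period
distortion), and tests 4-100 Hz bins against the variability of the
normalized spectrum in a 150-250 Hz control band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .config import AnalysisConfig
from .session import SessionRecord, UnitSpikeTrain


@dataclass
class SphpSegment:
    trial_index: int
    start: float
    end: float
    spike_times: np.ndarray   # within [start, end)

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def n_spikes(self) -> int:
        return int(np.asarray(self.spike_times).size)


@dataclass
class Burst:
    first_spike_index: int   # index into the segment's spike list
    n_spikes: int
    surprise: float
    start: float
    end: float


@dataclass
class BurstSet:
    bursts: List[Burst]
    burstiness: float                  # fraction of spikes inside bursts
    intra_burst_rate: float            # sp/s
    normalized_intra_burst_rate: float # intra-burst rate / mean rate


@dataclass
class SpectrumPeak:
    freq: float
    normalized_power: float
    band: str


@dataclass
class SpectrumResult:
    freqs: np.ndarray
    normalized_power: np.ndarray
    n_segments: int
    peaks: List[SpectrumPeak]
    control_mean: float
    control_sd: float
    threshold: float


@dataclass
class RampResult:
    slope: float      # sp/s per s
    p_value: float
    sign: str         # positive | negative | none


@dataclass
class RestSummary:
    mean_rate: float
    isi_cv: Optional[float]
    burst_set: Optional[BurstSet]
    spectrum: Optional[SpectrumResult]
    ramp: Optional[RampResult]
    notes: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------


def extract_sphp(session: SessionRecord,
                 unit: UnitSpikeTrain) -> List[SphpSegment]:
    """One segment per trial, [sphp_start, go_cue), half-open membership."""
    st = np.asarray(unit.spike_times)
    out = []
    for t in session.trials:
        inside = st[(st >= t.sphp_start) & (st < t.go_cue)]
        out.append(SphpSegment(trial_index=t.trial_index, start=t.sphp_start,
                               end=t.go_cue, spike_times=inside))
    return out


def mean_rate(segments: Sequence[SphpSegment]) -> float:
    """Pooled rate: total spikes over total duration (never a mean of
    per-segment rates)."""
    if not segments:
        raise ValueError("no segments")
    total_dur = sum(s.duration for s in segments)
    if total_dur <= 0:
        raise ValueError("zero total duration")
    return sum(s.n_spikes for s in segments) / total_dur


def isi_cv(segments: Sequence[SphpSegment]) -> float:
    """Coefficient of variation of ISIs pooled within segments (never
    across segment boundaries)."""
    isis = np.concatenate([np.diff(s.spike_times) for s in segments
                           if s.n_spikes >= 2] or [np.empty(0)])
    if isis.size < 3:
        raise ValueError("need at least 3 within-segment ISIs")
    return float(isis.std(ddof=0) / isis.mean())


# ---------------------------------------------------------------------------
# Poisson-surprise bursts


def poisson_surprise(n: int, duration: float, rate: float,
                     base: str = "natural") -> float:
    """Surprise of a candidate burst of ``n`` spikes spanning ``duration``.

    The burst is anchored on its first spike, so the chance quantity is
    the probability of observing at least the remaining n-1 spikes within
    ``duration`` under a Poisson train at ``rate``:
    S = -log P(N >= n-1), N ~ Poisson(rate * duration).
    """
    if duration <= 0 or rate <= 0:
        return 0.0
    logp = sps.poisson.logsf(n - 2, rate * duration)
    s = -logp
    return float(s / np.log(10)) if base == "log10" else float(s)


def _detect_bursts_in_segment(spikes: np.ndarray, rate: float,
                              config: AnalysisConfig) -> List[Burst]:
    """Greedy surprise maximization: seed on two consecutive ISIs shorter
    than half the mean ISI, extend the end one spike at a time while the
    surprise grows, then trim the start; accept at n >= burst_min_spikes
    and S >= threshold."""
    m = spikes.size
    if m < config.burst_min_spikes:
        return []
    isi = np.diff(spikes)
    mean_isi = 1.0 / rate
    base = config.surprise_log_base

    def S(i: int, j: int) -> float:
        return poisson_surprise(j - i + 1, spikes[j] - spikes[i], rate, base)

    bursts: List[Burst] = []
    i = 0
    while i < m - 2:
        if not (isi[i] < 0.5 * mean_isi and isi[i + 1] < 0.5 * mean_isi):
            i += 1
            continue
        lo, hi = i, i + 2
        best = S(lo, hi)
        # extend the end one spike at a time while surprise increases
        while hi + 1 < m:
            s = S(lo, hi + 1)
            if s > best:
                hi, best = hi + 1, s
            else:
                break
        # trim the start
        improved = True
        while improved and hi - lo + 1 > config.burst_min_spikes:
            improved = False
            s = S(lo + 1, hi)
            if s > best:
                lo, best, improved = lo + 1, s, True
        n = hi - lo + 1
        if n >= config.burst_min_spikes and best >= config.surprise_threshold:
            bursts.append(Burst(first_spike_index=lo, n_spikes=n,
                                surprise=best, start=spikes[lo],
                                end=spikes[hi]))
            i = hi + 1
        else:
            i += 1
    return bursts


def detect_bursts(segments: Sequence[SphpSegment], unit_rate: float,
                  config: Optional[AnalysisConfig] = None) -> BurstSet:
    config = config or AnalysisConfig()
    if unit_rate <= 0:
        raise ValueError("mean rate must be positive")
    bursts: List[Burst] = []
    total_spikes = 0
    burst_spikes = 0
    burst_time = 0.0
    for seg in segments:
        spikes = np.asarray(seg.spike_times)
        total_spikes += spikes.size
        for b in _detect_bursts_in_segment(spikes, unit_rate, config):
            bursts.append(b)
            burst_spikes += b.n_spikes
            burst_time += b.end - b.start
    burstiness = burst_spikes / total_spikes if total_spikes else 0.0
    intra = burst_spikes / burst_time if burst_time > 0 else 0.0
    return BurstSet(bursts=bursts, burstiness=burstiness,
                    intra_burst_rate=intra,
                    normalized_intra_burst_rate=intra / unit_rate)


# ---------------------------------------------------------------------------
# shuffle-normalized spectra


def _segment_windows(segments: Sequence[SphpSegment],
                     config: AnalysisConfig) -> List[np.ndarray]:
    """Cut each usable SPHP into non-overlapping binarized 1-kHz windows."""
    nfft = int(round(config.spectral_segment * 1000))
    wins = []
    for seg in segments:
        if seg.n_spikes < config.min_spikes_per_sphp_spectrum:
            continue
        rel = (np.asarray(seg.spike_times) - seg.start)
        n_win = int(seg.duration * 1000) // nfft
        if n_win == 0:
            continue
        idx = np.floor(rel * 1000).astype(int)
        train = np.bincount(idx[idx < n_win * nfft], minlength=n_win * nfft)
        train = np.minimum(train, 1).astype(float)
        for k in range(n_win):
            wins.append(train[k * nfft:(k + 1) * nfft])
    return wins


def _mean_periodogram(windows: List[np.ndarray], taper: np.ndarray) -> np.ndarray:
    acc = np.zeros(taper.size // 2 + 1)
    for w in windows:
        acc += np.abs(np.fft.rfft(w * taper)) ** 2
    return acc / len(windows)


def _assign_band(freq: float, edges: dict) -> str:
    best, best_d = "", np.inf
    for name, (lo, hi) in edges.items():
        if lo <= freq <= hi:
            return name
        d = min(abs(freq - lo), abs(freq - hi))
        if d < best_d:
            best, best_d = name, d
    return best


def shuffled_normalized_spectrum(segments: Sequence[SphpSegment],
                                 config: Optional[AnalysisConfig] = None,
                                 seed: int = 0) -> SpectrumResult:
    """Shuffle-normalized power spectrum with control-band significance.

    SPHPs with fewer than 4 spikes are excluded.  The control spectrum is
    the mean over ``n_isi_shuffles`` surrogates built by order-permuting
    the pooled within-SPHP ISIs, reconstructing a train, laying it onto
    the original segment durations and re-segmenting identically.
    """
    config = config or AnalysisConfig()
    nfft = int(round(config.spectral_segment * 1000))
    used = [s for s in segments
            if s.n_spikes >= config.min_spikes_per_sphp_spectrum
            and int(s.duration * 1000) >= nfft]
    windows = _segment_windows(used, config)
    if not windows:
        raise ValueError("no usable spectral segments")
    taper = np.hanning(nfft)
    freqs = np.fft.rfftfreq(nfft, d=0.001)
    primary = _mean_periodogram(windows, taper)

    # pooled within-segment ISIs + per-segment first-spike offsets
    isis = np.concatenate([np.diff(s.spike_times) for s in used
                           if s.n_spikes >= 2])
    durations = [s.duration for s in used]
    offsets = [float(s.spike_times[0] - s.start) for s in used]
    rng = np.random.default_rng(seed)
    control = np.zeros_like(primary)
    bounds = np.concatenate([[0.0], np.cumsum(durations)])
    for _ in range(config.n_isi_shuffles):
        shuf = rng.permutation(isis)
        # reconstructed train on a concatenated timeline, first spike at
        # the first segment's original offset
        train = offsets[0] + np.concatenate([[0.0], np.cumsum(shuf)])
        surr_segments = []
        for k, dur in enumerate(durations):
            lo, hi = bounds[k], bounds[k + 1]
            seg_spikes = train[(train >= lo) & (train < hi)] - lo
            surr_segments.append(SphpSegment(trial_index=-1, start=0.0,
                                             end=dur, spike_times=seg_spikes))
        surr_windows = _segment_windows(surr_segments, config)
        if surr_windows:
            control += _mean_periodogram(surr_windows, taper)
    control /= config.n_isi_shuffles
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(control > 0, primary / control, 1.0)

    cb = (freqs >= config.control_band[0]) & (freqs <= config.control_band[1])
    c_mean, c_sd = float(norm[cb].mean()), float(norm[cb].std(ddof=1))
    z = sps.norm.ppf(1 - 0.05 / config.spectral_bonferroni_n)
    threshold = c_mean + z * c_sd

    tb = (freqs >= config.test_band[0]) & (freqs <= config.test_band[1])
    sig = tb & (norm > threshold)
    peaks: List[SpectrumPeak] = []
    idx = np.flatnonzero(sig)
    if idx.size:
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in splits:
            j = run[np.argmax(norm[run])]
            peaks.append(SpectrumPeak(freq=float(freqs[j]),
                                      normalized_power=float(norm[j]),
                                      band=_assign_band(freqs[j],
                                                        config.band_edges)))
    return SpectrumResult(freqs=freqs, normalized_power=norm,
                          n_segments=len(windows), peaks=peaks,
                          control_mean=c_mean, control_sd=c_sd,
                          threshold=float(threshold))


# ---------------------------------------------------------------------------
# ramps


def detect_ramp(segments: Sequence[SphpSegment],
                config: Optional[AnalysisConfig] = None) -> RampResult:
    """Regress firing rate (250-ms bins) on time from SPHP onset, pooled
    across segments; assign a sign when two-sided p < 0.05."""
    config = config or AnalysisConfig()
    bin_s = config.ramp_bin
    xs, ys = [], []
    for seg in segments:
        n_bins = int(seg.duration / bin_s)
        if n_bins == 0:
            continue
        rel = np.asarray(seg.spike_times) - seg.start
        counts = np.bincount(np.floor(rel / bin_s).astype(int),
                             minlength=n_bins)[:n_bins]
        xs.append((np.arange(n_bins) + 0.5) * bin_s)
        ys.append(counts / bin_s)
    if not xs or sum(x.size for x in xs) < 10:
        raise ValueError("need at least 10 pooled rate bins")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    fit = sps.linregress(x, y)
    sign = "none"
    if fit.pvalue < config.ramp_alpha:
        sign = "positive" if fit.slope > 0 else "negative"
    return RampResult(slope=float(fit.slope), p_value=float(fit.pvalue),
                      sign=sign)


# ---------------------------------------------------------------------------


def summarize_rest(session: SessionRecord, unit: UnitSpikeTrain,
                   config: Optional[AnalysisConfig] = None,
                   seed: int = 0) -> RestSummary:
    """Full resting-state summary for one unit; stages that cannot run on
    the available data are skipped with a note."""
    config = config or AnalysisConfig()
    segments = extract_sphp(session, unit)
    rate = mean_rate(segments)
    notes = []
    try:
        cv = isi_cv(segments)
    except ValueError as e:
        cv, _ = None, notes.append(f"isi_cv: {e}")
    try:
        bursts = detect_bursts(segments, rate, config)
    except ValueError as e:
        bursts, _ = None, notes.append(f"bursts: {e}")
    try:
        spectrum = shuffled_normalized_spectrum(segments, config, seed=seed)
    except ValueError as e:
        spectrum, _ = None, notes.append(f"spectrum: {e}")
    try:
        ramp = detect_ramp(segments, config)
    except ValueError as e:
        ramp, _ = None, notes.append(f"ramp: {e}")
    return RestSummary(mean_rate=rate, isi_cv=cv, burst_set=bursts,
                       spectrum=spectrum, ramp=ramp, notes=notes)
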