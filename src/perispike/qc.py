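"""Unit quality control: waveform-feature screening, firing-rate gating,
and refractory-period checks.

Median waveforms are summarized by three shape features (half-width of
the dominant deflection, normalized peak-trough asymmetry, normalized
pre/after-hyperpolarization asymmetry); density-based clustering in that
feature space flags units whose waveform shape is anomalous for the
population (e.g. fiber rather than somatic recordings).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .stats import mad


@dataclass
class WaveformFeatures:
    half_width: float        # ms
    peak_trough_diff: float  # (|peak| - |trough|) / (|peak| + |trough|)
    hyperpol_diff: float     # (pre - after) / (pre + after)
    outlier: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.half_width, self.peak_trough_diff,
                         self.hyperpol_diff])


def waveform_features(median_waveform: Sequence[float],
                      sample_interval: float) -> WaveformFeatures:
    """Extract the three shape features from a median waveform.

    ``sample_interval`` is in ms.  The dominant deflection is the global
    extremum of larger magnitude; the flanking same-sign extrema around
    it define the pre- and after-hyperpolarization peaks.
    """
    w = np.asarray(median_waveform, dtype=float)
    if w.size < 5 or np.ptp(w) == 0:
        raise ValueError("flat or degenerate waveform")
    peak, trough = float(w.max()), float(w.min())
    i_ext = int(np.argmin(w)) if abs(trough) >= abs(peak) else int(np.argmax(w))
    ext = w[i_ext]

    # half-width of the dominant deflection at half its extremum
    half = ext / 2.0
    crossed = (w <= half) if ext < 0 else (w >= half)
    left = i_ext
    while left > 0 and crossed[left - 1]:
        left -= 1
    right = i_ext
    while right < w.size - 1 and crossed[right + 1]:
        right += 1
    half_width = (right - left + 1) * sample_interval

    denom = abs(peak) + abs(trough)
    peak_trough_diff = (abs(peak) - abs(trough)) / denom

    # flanking extrema of sign opposite to the dominant deflection
    sign = -np.sign(ext)
    before = w[:left] * sign
    after = w[right + 1:] * sign
    pre = float(before.max()) if before.size else 0.0
    post = float(after.max()) if after.size else 0.0
    s = pre + post
    hyperpol_diff = (pre - post) / s if s != 0 else 0.0
    return WaveformFeatures(half_width=half_width,
                            peak_trough_diff=peak_trough_diff,
                            hyperpol_diff=hyperpol_diff)


def detect_waveform_outliers(features: Sequence[WaveformFeatures],
                             eps: float = 4.0,
                             min_neighbors: int = 4) -> np.ndarray:
    """Density-based outlier flags over MAD-standardized features.

    Each feature dimension is divided by its MAD before clustering;
    points labeled as noise (lacking ``min_neighbors`` points within
    ``eps``) are outliers.
    """
    from sklearn.cluster import DBSCAN

    if len(features) < 10:
        raise ValueError("need at least 10 units for outlier screening")
    x = np.vstack([f.as_array() for f in features])
    scale = np.array([mad(x[:, j]) for j in range(x.shape[1])])
    scale[scale == 0] = 1.0
    xs = (x - np.median(x, axis=0)) / scale
    if np.allclose(xs, xs[0]):
        return np.zeros(len(features), dtype=bool)
    labels = DBSCAN(eps=eps, min_samples=min_neighbors).fit_predict(xs)
    mask = labels == -1
    for f, m in zip(features, mask):
        f.outlier = bool(m)
    return mask


def firing_rate_gate(rates: Sequence[float],
                     k: float = 1.5) -> Tuple[float, float, np.ndarray]:
    """Acceptable-rate band: median +- k*MAD; returns (low, high, mask)."""
    r = np.asarray(rates, dtype=float)
    if r.size < 5:
        raise ValueError("need at least 5 units to define a rate gate")
    med = float(np.median(r))
    m = mad(r)
    low, high = med - k * m, med + k * m
    return low, high, (r >= low) & (r <= high)


def refractory_screen(spike_times: Sequence[float],
                      refractory: float = 0.0015,
                      ceiling: float = 0.005) -> bool:
    """Pass iff the fraction of ISIs shorter than ``refractory`` is at or
    below ``ceiling``."""
    st = np.asarray(spike_times, dtype=float)
    isi = np.diff(st)
    if isi.size < 100:
        raise ValueError("need at least 100 ISIs for the refractory screen")
    return float(np.mean(isi < refractory)) <= ceiling
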