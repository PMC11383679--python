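"""Spike density functions.

A spike train is converted to a continuous firing-rate estimate by
convolving its 1-kHz delta function with a Gaussian kernel
(sigma = 25 ms by default).  Each spike contributes unit mass, so the
trace integrates to the spike count and is expressed in spikes/s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .config import AnalysisConfig

KERNEL_TRUNC_SIGMAS = 4.0


@dataclass
class SDFTrace:
    """A spike density function on a uniform 1-ms grid.

    ``time_grid`` holds integer milliseconds relative to ``align_event``
    (the event's time is subtracted out); ``values`` are in spikes/s.
    """

    align_event: str
    time_grid: np.ndarray          # ms, int, 1-ms step
    values: np.ndarray             # sp/s
    n_trials: int
    flavor: str = "single_trial"   # or "mean"
    per_point_sd: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time_grid = np.asarray(self.time_grid)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_grid.size > 1 and not np.all(np.diff(self.time_grid) == 1):
            raise ValueError("SDF grid must be uniform at 1 ms")
        if self.time_grid.shape != self.values.shape:
            raise ValueError("grid/value shape mismatch")

    def window(self, t0: int, t1: int) -> np.ndarray:
        """Values on [t0, t1) ms; both must lie on the grid."""
        g0 = int(self.time_grid[0])
        i0, i1 = t0 - g0, t1 - g0
        if i0 < 0 or i1 > self.values.size:
            raise ValueError("window outside trace")
        return self.values[i0:i1]


def gaussian_kernel(sigma_s: float) -> np.ndarray:
    """Unit-mass Gaussian kernel sampled at 1 ms, truncated at +-4 sigma."""
    sigma_ms = sigma_s * 1000.0
    radius = int(np.ceil(KERNEL_TRUNC_SIGMAS * sigma_ms))
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma_ms) ** 2)
    return k / k.sum()


def compute_sdf(spikes: Sequence[float], align_time: float,
                window: Tuple[int, int], config: AnalysisConfig,
                align_event: str = "movement_onset") -> SDFTrace:
    """Single-trial SDF on ``window`` (ms, half-open) around ``align_time``.

    Spikes outside the window still contribute through the kernel tails,
    so the trace has no edge deficit within the window itself.
    """
    w0, w1 = int(window[0]), int(window[1])
    if w1 <= w0:
        raise ValueError("empty SDF window")
    kernel = gaussian_kernel(config.sdf_sigma)
    radius = (kernel.size - 1) // 2

    rel_ms = np.round((np.asarray(spikes, dtype=float) - align_time)
                      * 1000.0).astype(int)
    # counts on an extended grid so kernel tails from outside spikes count
    lo, hi = w0 - radius, w1 + radius
    keep = (rel_ms >= lo) & (rel_ms < hi)
    counts = np.bincount(rel_ms[keep] - lo, minlength=hi - lo).astype(float)
    dens = np.convolve(counts, kernel, mode="same")[radius:radius + (w1 - w0)]
    return SDFTrace(align_event=align_event,
                    time_grid=np.arange(w0, w1),
                    values=dens * 1000.0,   # per-ms mass -> sp/s
                    n_trials=1, flavor="single_trial")


def mean_sdf(traces: Sequence[SDFTrace],
             min_trials: int = 1) -> SDFTrace:
    """Pointwise mean (and SD) across single-trial SDFs on a common grid."""
    if len(traces) < min_trials:
        raise ValueError(
            f"need at least {min_trials} trials, got {len(traces)}")
    grid = traces[0].time_grid
    for t in traces[1:]:
        if t.time_grid.shape != grid.shape or not np.array_equal(t.time_grid, grid):
            raise ValueError("mismatched SDF grids")
    stack = np.vstack([t.values for t in traces])
    return SDFTrace(align_event=traces[0].align_event, time_grid=grid,
                    values=stack.mean(axis=0), n_trials=len(traces),
                    flavor="mean", per_point_sd=stack.std(axis=0, ddof=1)
                    if len(traces) > 1 else np.zeros_like(grid, dtype=float))
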