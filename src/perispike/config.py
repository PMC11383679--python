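"""Analysis configuration.

All tunable constants of the pipeline live in :class:`AnalysisConfig`.
Defaults reproduce the published analysis choices (25-ms SDF kernel,
700-ms baseline window, 60-ms minimum response duration, surprise
threshold of 5, 512-ms spectral segments, ...).  Every field can be
overridden from a flat ``key = value`` text file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union


@dataclass
class AnalysisConfig:
    # spike density function
    sdf_sigma: float = 0.025          # s, Gaussian kernel SD
    # perimovement detection
    baseline_window: float = 0.700    # s, trend window ending at test-window start
    min_response_duration: float = 0.060   # s, minimum significant run
    omnibus_alpha_response: float = 0.001  # omnibus level before Bonferroni
    per_point_test: str = "ttest"     # "ttest" (across-trial) or "zscore" (baseline SD)
    # single-trial step-kernel fit
    step_kernel_length: float = 0.200  # s: 100 low + 100 high points at 1 ms
    # resting-state spectra
    spectral_segment: float = 0.512   # s, non-overlapping FFT segments
    n_isi_shuffles: int = 100
    spectral_bonferroni_n: int = 51   # divisor for the 4-100 Hz omnibus test
    min_spikes_per_sphp_spectrum: int = 4
    control_band: tuple = (150.0, 250.0)   # Hz
    test_band: tuple = (4.0, 100.0)        # Hz
    band_edges: dict = field(default_factory=lambda: {
        "theta": (4.0, 7.9),
        "alpha": (8.0, 12.0),
        "low_beta": (12.5, 20.0),
        "high_beta": (20.5, 30.0),
        "gamma": (30.5, 100.0),
    })
    # burst detection
    surprise_threshold: float = 5.0   # natural-log Poisson surprise
    surprise_log_base: str = "natural"  # "natural" or "log10"
    burst_min_spikes: int = 4
    # ramps
    ramp_bin: float = 0.250           # s, rate bins for the ramp regression
    ramp_alpha: float = 0.05
    # secondary tests
    secondary_alpha: float = 0.05
    # unit QC
    refractory_period: float = 0.0015     # s
    refractory_ceiling: float = 0.005     # max fraction of violating ISIs
    rate_gate_k: float = 1.5              # x MAD around the median rate
    dbscan_eps: float = 4.0               # MAD-standardized feature units
    dbscan_min_neighbors: int = 4
    # behavioral exclusions
    trial_outlier_k: float = 6.0          # x MAD from the mean
    outlier_center: str = "mean"          # "mean" (as published) or "median"
    response_windows: dict = field(default_factory=lambda: {"pre": 1.0, "post": 3.0})
    assisted_return_threshold: float = 6.0  # s
    # directionality
    directionality_window: float = 0.300  # s from earliest response onset
    min_trials_per_direction: int = 10
    # de-jittering
    peak_prominence_frac: float = 0.10    # fraction of single-trial dynamic range

    def __post_init__(self) -> None:
        for name in ("sdf_sigma", "baseline_window", "min_response_duration",
                     "spectral_segment", "refractory_period", "ramp_bin",
                     "directionality_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.test_band
        if not (0 <= lo < hi <= 500):
            raise ValueError("test_band must lie within [0, Nyquist]")
        lo, hi = self.control_band
        if not (0 <= lo < hi <= 500):
            raise ValueError("control_band must lie within [0, Nyquist]")


def save_config(config: AnalysisConfig, path: Union[str, Path]) -> None:
    """Write a flat ``key = value`` config file."""
    lines = []
    for f in dataclasses.fields(config):
        lines.append(f"{f.name} = {getattr(config, f.name)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: Union[str, Path]) -> AnalysisConfig:
    """Read a flat ``key = value`` file; unknown keys raise, missing keys default."""
    import ast

    overrides = {}
    valid = {f.name for f in dataclasses.fields(AnalysisConfig)}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in valid:
            raise ValueError(f"unknown config key: {key}")
        overrides[key] = ast.literal_eval(val)
    return AnalysisConfig(**overrides)
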