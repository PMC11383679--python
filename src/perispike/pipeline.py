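"""End-to-end orchestration: sessions -> QC -> behavior -> rest ->
perimovement responses -> trial-by-trial timing -> population tables.

Every exclusion is logged with the rule that fired; a unit that fails a
stage is skipped for that stage and the pipeline continues.  All outputs
are plain delimited tables, deterministic under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .behavior import screen_trials
from .config import AnalysisConfig
from .qc import (detect_waveform_outliers, firing_rate_gate,
                 refractory_screen, waveform_features)
from .responses import (analyze_direction, test_directionality,
                        trial_traces_for_direction)
from .rest import extract_sphp, mean_rate, summarize_rest
from .session import SessionRecord, read_session
from .timing import dejitter, event_locking, single_trial_onset


@dataclass
class PipelineReport:
    units: pd.DataFrame
    responses: pd.DataFrame
    locking: pd.DataFrame
    dejittered: pd.DataFrame
    population: Dict[str, pd.DataFrame]
    log: List[str] = field(default_factory=list)
    provenance: Dict[str, str] = field(default_factory=dict)

    def write(self, out_dir: Union[str, Path]) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("units", "responses", "locking", "dejittered"):
            getattr(self, name).to_csv(out / f"{name}.tsv", sep="\t",
                                       index=False, lineterminator="\n")
        for name, df in self.population.items():
            df.to_csv(out / f"population_{name}.tsv", sep="\t",
                      lineterminator="\n")
        (out / "log.txt").write_text("\n".join(self.log) + "\n")
        (out / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True) + "\n")


def _config_hash(config: AnalysisConfig) -> str:
    import dataclasses
    payload = {f.name: repr(getattr(config, f.name))
               for f in dataclasses.fields(config)}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(sessions: Sequence[Union[SessionRecord, str, Path]],
                 config: Optional[AnalysisConfig] = None,
                 seed: int = 0) -> PipelineReport:
    config = config or AnalysisConfig()
    records: List[SessionRecord] = [
        s if isinstance(s, SessionRecord) else read_session(s)
        for s in sessions]
    log: List[str] = []

    # --- stage 1: per-unit QC inputs gathered across sessions per state
    unit_rows = []
    keep: Dict[tuple, bool] = {}
    per_state_rates: Dict[str, List[tuple]] = {"pre": [], "post": []}
    for rec in records:
        for unit in rec.units:
            key = (rec.session_id, unit.unit_id)
            keep[key] = True
            try:
                ok = refractory_screen(unit.spike_times,
                                       config.refractory_period,
                                       config.refractory_ceiling)
            except ValueError:
                ok = True
                log.append(f"{key}: too few ISIs for refractory screen")
            if not ok:
                keep[key] = False
                log.append(f"{key}: excluded (refractory violations)")
                continue
            segs = extract_sphp(rec, unit)
            try:
                rate = mean_rate(segs)
            except ValueError:
                keep[key] = False
                log.append(f"{key}: excluded (no SPHP data)")
                continue
            per_state_rates[rec.state].append((key, rate))

    for state, pairs in per_state_rates.items():
        if len(pairs) >= 5:
            lo, hi, mask = firing_rate_gate([r for _, r in pairs],
                                            config.rate_gate_k)
            for (key, rate), ok in zip(pairs, mask):
                if not ok:
                    keep[key] = False
                    log.append(f"{key}: excluded (rate {rate:.1f} outside "
                               f"[{lo:.1f}, {hi:.1f}] {state} gate)")

    # waveform outlier screen, per state, where waveforms exist
    for state in ("pre", "post"):
        feats, keys = [], []
        for rec in records:
            if rec.state != state:
                continue
            for unit in rec.units:
                if unit.median_waveform is not None and \
                        keep[(rec.session_id, unit.unit_id)]:
                    feats.append(waveform_features(unit.median_waveform, 0.025))
                    keys.append((rec.session_id, unit.unit_id))
        if len(feats) >= 10:
            mask = detect_waveform_outliers(feats, config.dbscan_eps,
                                            config.dbscan_min_neighbors)
            for key, bad in zip(keys, mask):
                if bad:
                    keep[key] = False
                    log.append(f"{key}: excluded (waveform outlier)")

    # --- stage 2: per-session analysis
    resp_rows, lock_rows, dejit_rows = [], [], []
    for si, rec in enumerate(records):
        metrics = screen_trials(rec.trials, config, rec.state)
        valid_idx = {m.trial_index for m in metrics if m.valid}
        for m in metrics:
            if not m.valid:
                log.append(f"{rec.session_id} trial {m.trial_index}: "
                           f"excluded ({m.exclusion_reason})")
        valid_trials = [t for t in rec.trials if t.trial_index in valid_idx]

        for unit in rec.units:
            key = (rec.session_id, unit.unit_id)
            if not keep[key]:
                continue
            rest = summarize_rest(rec, unit, config, seed=seed + 17 * si)
            row = dict(session_id=rec.session_id, unit_id=unit.unit_id,
                       state=rec.state, mean_rate=rest.mean_rate,
                       isi_cv=rest.isi_cv,
                       burstiness=rest.burst_set.burstiness
                       if rest.burst_set else np.nan,
                       norm_intra_burst_rate=(
                           rest.burst_set.normalized_intra_burst_rate
                           if rest.burst_set else np.nan),
                       n_spectral_peaks=len(rest.spectrum.peaks)
                       if rest.spectrum else np.nan,
                       peak_bands=";".join(p.band for p in rest.spectrum.peaks)
                       if rest.spectrum else "",
                       ramp_sign=rest.ramp.sign if rest.ramp else "",
                       ramp_slope=rest.ramp.slope if rest.ramp else np.nan)
            unit_rows.append(row)

            profiles = {}
            trials_by_dir = {}
            for direction in ("left", "right"):
                dir_trials = [t for t in valid_trials
                              if t.target == direction
                              and t.movement_onset is not None
                              and t.movement_offset is not None]
                trials_by_dir[direction] = dir_trials
                if len(dir_trials) < config.min_trials_per_direction:
                    log.append(f"{key} {direction}: skipped "
                               f"({len(dir_trials)} < "
                               f"{config.min_trials_per_direction} trials)")
                    profiles[direction] = None
                    continue
                profile = analyze_direction(rec, unit, direction,
                                            valid_trials, config)
                profiles[direction] = profile

            d300 = dwhole = None
            if all(len(trials_by_dir[d]) >= config.min_trials_per_direction
                   for d in ("left", "right")):
                d300, dwhole = test_directionality(unit, profiles,
                                                   trials_by_dir, config)

            for direction, profile in profiles.items():
                if profile is None:
                    continue
                resp_rows.append(dict(
                    session_id=rec.session_id, unit_id=unit.unit_id,
                    state=rec.state, direction=direction, rtype=profile.rtype,
                    n_segments=len(profile.segments),
                    onset_latency_move=profile.onset_latency_move,
                    magnitude=profile.magnitude, fwhm=profile.fwhm,
                    fwhm_truncated=profile.fwhm_truncated,
                    directional_300ms=d300, directional_whole=dwhole))
                if profile.rtype == "none":
                    continue

                trials_d, traces = trial_traces_for_direction(
                    rec, unit, direction, valid_trials, config)
                st = np.asarray(unit.spike_times)
                onsets = []
                for t, tr in zip(trials_d, traces):
                    n_in = int(np.sum((st >= t.go_cue)
                                      & (st < t.movement_offset)))
                    onsets.append(single_trial_onset(
                        tr, t, profile.rtype, config, n_spikes_in_span=n_in))
                try:
                    lock = event_locking(onsets, trials_d, config)
                    lock_rows.append(dict(
                        session_id=rec.session_id, unit_id=unit.unit_id,
                        state=rec.state, direction=direction,
                        slope_cue_resp=lock.slope_cue_resp,
                        slope_resp_mvt=lock.slope_resp_mvt,
                        category=lock.category, eli=lock.eli,
                        residual_iqr=lock.residual_iqr,
                        n_trials=lock.n_trials_used))
                except ValueError as e:
                    log.append(f"{key} {direction}: locking skipped ({e})")

                if profile.rtype in ("incr", "decr"):
                    try:
                        dj = dejitter(traces, onsets, trials_d, profile.rtype,
                                      profile.trend, config)
                        dejit_rows.append(dict(
                            session_id=rec.session_id, unit_id=unit.unit_id,
                            state=rec.state, direction=direction,
                            magnitude=dj.magnitude, fwhm=dj.fwhm,
                            n_trials=dj.n_trials))
                    except ValueError as e:
                        log.append(f"{key} {direction}: de-jitter skipped "
                                   f"({e})")

    units_df = pd.DataFrame(unit_rows)
    resp_df = pd.DataFrame(resp_rows)
    lock_df = pd.DataFrame(lock_rows)
    dejit_df = pd.DataFrame(dejit_rows)

    population: Dict[str, pd.DataFrame] = {}
    if not resp_df.empty:
        population["rtype_by_state"] = pd.crosstab(resp_df["rtype"],
                                                   resp_df["state"])
    if not units_df.empty:
        summary = units_df.groupby("state").agg(
            n_units=("unit_id", "size"), mean_rate=("mean_rate", "mean"),
            isi_cv=("isi_cv", "mean"), burstiness=("burstiness", "mean"))
        population["rest_by_state"] = summary

    return PipelineReport(
        units=units_df, responses=resp_df, locking=lock_df,
        dejittered=dejit_df, population=population, log=log,
        provenance=dict(config_hash=_config_hash(config), seed=str(seed),
                        package_version=__version__,
                        numpy=np.__version__, pandas=pd.__version__))
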