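"""Session domain types and the on-disk session bundle.

A recording session couples per-trial behavioral event times with the
spike trains of simultaneously recorded single units, all on one session
clock in seconds.  Spike stamps carry 1-ms resolution, so the bundle
stores every time rounded (half-even) to 3 decimals and a write/read
round trip is the identity.

Bundle layout (a directory)::

    meta.txt            key = value (session_id, subject_id, state)
    trials.tsv          one row per trial
    units/<id>.spikes.tsv       one spike time per line
    units/<id>.waveform.tsv     optional median waveform samples
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_TARGETS = ("left", "right")
VALID_OUTCOMES = ("correct", "wrong_target", "timeout", "hold_fail")
VALID_STATES = ("pre", "post")

_TRIAL_COLUMNS = [
    "trial_index", "target", "sphp_start", "go_cue", "movement_onset",
    "movement_offset", "reward", "return_complete", "outcome",
]


class SessionFormatError(ValueError):
    """A session bundle violates the format or a type invariant."""


def _round_ms(t: float) -> float:
    """Round a time in seconds to 1-ms precision, ties to even."""
    return round(t, 3)


@dataclass
class TrialEvents:
    """Event times of one behavioral trial (session clock, seconds).

    Error trials may lack movement events; downstream stages must
    tolerate ``None`` there.
    """

    trial_index: int
    target: str
    sphp_start: float
    go_cue: float
    movement_onset: Optional[float] = None
    movement_offset: Optional[float] = None
    reward: Optional[float] = None
    return_complete: Optional[float] = None
    outcome: str = "correct"

    def validate(self) -> None:
        if self.target not in VALID_TARGETS:
            raise SessionFormatError(
                f"trial {self.trial_index}: bad target {self.target!r}")
        if self.outcome not in VALID_OUTCOMES:
            raise SessionFormatError(
                f"trial {self.trial_index}: bad outcome {self.outcome!r}")
        if not self.sphp_start < self.go_cue:
            raise SessionFormatError(
                f"trial {self.trial_index}: sphp_start must precede go_cue")
        if self.movement_onset is not None:
            if not self.go_cue < self.movement_onset:
                raise SessionFormatError(
                    f"trial {self.trial_index}: movement_onset before go_cue")
            if self.movement_offset is not None and \
                    not self.movement_onset < self.movement_offset:
                raise SessionFormatError(
                    f"trial {self.trial_index}: movement_offset before onset")

    @property
    def sphp_duration(self) -> float:
        return self.go_cue - self.sphp_start


@dataclass
class UnitSpikeTrain:
    """Spike stamps of one sorted unit, strictly increasing, 1-ms resolution."""

    unit_id: str
    spike_times: np.ndarray
    median_waveform: Optional[np.ndarray] = None
    mean_rate_hint: Optional[float] = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)

    def validate(self, repair: bool = False) -> None:
        st = self.spike_times
        if st.ndim != 1:
            raise SessionFormatError(f"unit {self.unit_id}: spikes must be 1-D")
        if st.size and np.any(np.diff(st) <= 0):
            if repair:
                logger.warning("unit %s: repairing unsorted/duplicate spikes",
                               self.unit_id)
                self.spike_times = np.unique(np.round(st, 3))
            else:
                raise SessionFormatError(
                    f"unit {self.unit_id}: spike times not strictly increasing")


@dataclass
class SessionRecord:
    """One recording session: trials plus unit spike trains on a common clock."""

    session_id: str
    subject_id: str
    state: str
    trials: List[TrialEvents] = field(default_factory=list)
    units: List[UnitSpikeTrain] = field(default_factory=list)

    def validate(self) -> None:
        if self.state not in VALID_STATES:
            raise SessionFormatError(f"bad state {self.state!r}")
        if not self.trials:
            raise SessionFormatError("session must contain at least one trial")
        starts = [t.sphp_start for t in self.trials]
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise SessionFormatError("trials not sorted by sphp_start")
        for trial in self.trials:
            trial.validate()
        lo, hi = self.time_bounds()
        for unit in self.units:
            unit.validate()
            st = unit.spike_times
            if st.size and (st[0] < lo or st[-1] > hi):
                raise SessionFormatError(
                    f"unit {unit.unit_id}: spikes outside session bounds")

    def time_bounds(self) -> tuple:
        """Session time span covered by trials (with a 30-s margin each side)."""
        lo = min(t.sphp_start for t in self.trials) - 30.0
        events = []
        for t in self.trials:
            events.extend(x for x in (t.go_cue, t.movement_offset,
                                      t.reward, t.return_complete)
                          if x is not None)
        return lo, max(events) + 30.0

    def unit(self, unit_id: str) -> UnitSpikeTrain:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)


# ---------------------------------------------------------------------------
# bundle I/O


def write_session(record: SessionRecord, path: Union[str, Path]) -> None:
    """Write a session bundle directory; deterministic byte-for-byte."""
    record.validate()
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    (root / "meta.txt").write_text(
        f"session_id = {record.session_id}\n"
        f"subject_id = {record.subject_id}\n"
        f"state = {record.state}\n")

    def fmt(x: Optional[float]) -> str:
        return "" if x is None else f"{_round_ms(x):.3f}"

    rows = []
    for t in record.trials:
        rows.append([t.trial_index, t.target, fmt(t.sphp_start), fmt(t.go_cue),
                     fmt(t.movement_onset), fmt(t.movement_offset),
                     fmt(t.reward), fmt(t.return_complete), t.outcome])
    df = pd.DataFrame(rows, columns=_TRIAL_COLUMNS)
    df.to_csv(root / "trials.tsv", sep="\t", index=False, lineterminator="\n")

    units_dir = root / "units"
    units_dir.mkdir(exist_ok=True)
    for u in record.units:
        lines = "".join(f"{_round_ms(s):.3f}\n" for s in u.spike_times)
        (units_dir / f"{u.unit_id}.spikes.tsv").write_text(lines)
        if u.median_waveform is not None:
            wf = "".join(f"{v:.6g}\n" for v in u.median_waveform)
            (units_dir / f"{u.unit_id}.waveform.tsv").write_text(wf)


def read_session_nwb(path: Union[str, Path]) -> SessionRecord:
    """Adapter stub for Neurodata Without Borders files.

    The intended mapping, for environments with an NWB reader installed:

    * ``nwbfile.trials`` columns -> :class:`TrialEvents` fields
      (``start_time`` + hold columns -> ``sphp_start``/``go_cue``;
      movement/reward columns by their task names; outcome string as-is);
    * ``nwbfile.units`` ``spike_times`` per unit -> :class:`UnitSpikeTrain`
      (rounded to 1 ms), ``waveform_mean`` -> ``median_waveform``;
    * session/subject identifiers from the file metadata, with the
      pre/post state carried in the session description.

    Not implemented here: the analysis pipeline consumes the plain-text
    session bundle instead.
    """
    raise NotImplementedError(
        "NWB ingestion is documented but not implemented; convert to a "
        "session bundle (write_session) instead")


def read_session(path: Union[str, Path]) -> SessionRecord:
    """Read a session bundle written by :func:`write_session`."""
    root = Path(path)
    if not root.is_dir():
        raise SessionFormatError(f"no session bundle at {path}")

    meta = {}
    for raw in (root / "meta.txt").read_text().splitlines():
        if "=" in raw:
            k, v = (s.strip() for s in raw.split("=", 1))
            meta[k] = v
    for key in ("session_id", "subject_id", "state"):
        if key not in meta:
            raise SessionFormatError(f"meta.txt missing required field {key!r}")
    known = {"session_id", "subject_id", "state"}
    for key in set(meta) - known:
        logger.warning("meta.txt: ignoring unknown field %r", key)

    df = pd.read_csv(root / "trials.tsv", sep="\t", dtype={"target": str,
                                                           "outcome": str})
    for col in _TRIAL_COLUMNS:
        if col not in df.columns:
            raise SessionFormatError(f"trials.tsv missing column {col!r}")
    for col in set(df.columns) - set(_TRIAL_COLUMNS):
        logger.warning("trials.tsv: ignoring unknown column %r", col)

    def opt(v) -> Optional[float]:
        return None if (v is None or (isinstance(v, float) and math.isnan(v))) \
            else float(v)

    trials = [TrialEvents(trial_index=int(r.trial_index), target=r.target,
                          sphp_start=float(r.sphp_start), go_cue=float(r.go_cue),
                          movement_onset=opt(r.movement_onset),
                          movement_offset=opt(r.movement_offset),
                          reward=opt(r.reward),
                          return_complete=opt(r.return_complete),
                          outcome=r.outcome)
              for r in df.itertuples()]

    units = []
    units_dir = root / "units"
    if units_dir.is_dir():
        for f in sorted(units_dir.glob("*.spikes.tsv")):
            uid = f.name[:-len(".spikes.tsv")]
            txt = f.read_text().split()
            spikes = np.array([float(s) for s in txt], dtype=float)
            wf_file = units_dir / f"{uid}.waveform.tsv"
            wf = None
            if wf_file.exists():
                wf = np.array([float(s) for s in wf_file.read_text().split()])
            u = UnitSpikeTrain(unit_id=uid, spike_times=spikes,
                               median_waveform=wf)
            u.validate(repair=True)
            units.append(u)

    record = SessionRecord(session_id=meta["session_id"],
                           subject_id=meta["subject_id"], state=meta["state"],
                           trials=trials, units=units)
    record.validate()
    return record
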