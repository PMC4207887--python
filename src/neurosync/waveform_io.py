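"""Plain-text I/O for synchronized respiratory waveform recordings.

A recording couples the diaphragm electrical activity (EAdi, μV), airway
pressure (Paw, cmH2O) and optionally flow (L/min), sampled uniformly
(clinically 62.5 Hz from the ventilator's serial stream). On disk a
recording is one CSV with columns ``time,eadi,paw[,flow]`` plus a JSON
sidecar ``<name>.meta.json`` carrying the sampling rate, units, PEEP,
ventilator mode and subject id. Event annotations (ground truth from the
simulator, or external labels) live in a separate JSON file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError

DEFAULT_FS_HZ = 62.5

_CHANNEL_UNITS = {"eadi": "uV", "paw": "cmH2O", "flow": "L/min"}


@dataclass
class SampledSignal:
    """One uniformly sampled channel.

    Sample ``i`` occurs at time ``t0 + i / fs`` seconds; there are no gaps.
    """

    name: str
    unit: str
    fs: float
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not self.fs > 0:
            raise ConfigError(f"sampling rate must be positive, got {self.fs}")
        if self.values.ndim != 1 or self.values.size == 0:
            raise ConfigError(f"signal '{self.name}' must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            bad = int(np.flatnonzero(~np.isfinite(self.values))[0])
            raise ConfigError(f"signal '{self.name}' has a non-finite sample at index {bad}")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in the recording clock (seconds)."""
        return self.t0 + np.arange(self.n) / self.fs


@dataclass
class Recording:
    """Synchronized EAdi/Paw(/flow) channels plus metadata.

    ``meta`` keys in use: ``fs_hz``, ``units``, ``peep_cmh2o``, ``mode``,
    ``subject``.
    """

    eadi: SampledSignal
    paw: SampledSignal
    flow: Optional[SampledSignal] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        chans = [self.eadi, self.paw] + ([self.flow] if self.flow is not None else [])
        if len({c.n for c in chans}) != 1:
            raise ConfigError("channels are not synchronized: unequal lengths")
        if len({c.fs for c in chans}) != 1:
            raise ConfigError("channels are not synchronized: unequal sampling rates")
        if len({c.t0 for c in chans}) != 1:
            raise ConfigError("channels are not synchronized: unequal start times")

    @property
    def fs(self) -> float:
        return self.eadi.fs

    @property
    def n(self) -> int:
        return self.eadi.n

    @property
    def t0(self) -> float:
        return self.eadi.t0

    @property
    def duration_s(self) -> float:
        return self.eadi.duration_s


@dataclass
class AnnotationSet:
    """Event-level annotations for one recording.

    ``neural_events``: (onset_s, peak_s, cycleoff_s) per neural effort;
    ``vent_events``: (trigger_s, cycleoff_s) per ventilator assist;
    ``labels``: (time_s, class) for injected/annotated asynchronies.
    """

    neural_events: list = field(default_factory=list)
    vent_events: list = field(default_factory=list)
    labels: list = field(default_factory=list)

    def validate(self, duration_s: float | None = None) -> None:
        for ev in self.neural_events:
            onset, peak, cyc = ev
            if not onset < peak < cyc:
                raise ConfigError(f"neural event times not strictly increasing: {ev}")
        for trig, cyc in self.vent_events:
            if not trig < cyc:
                raise ConfigError(f"vent event times not increasing: {(trig, cyc)}")
        if duration_s is not None:
            times = [t for ev in self.neural_events for t in ev]
            times += [t for ev in self.vent_events for t in ev]
            times += [t for t, _ in self.labels]
            if times and (min(times) < 0 or max(times) > duration_s + 1e-9):
                raise ConfigError("annotation outside recording duration")

    def to_dict(self) -> dict:
        return {
            "neural_events": [list(map(float, ev)) for ev in self.neural_events],
            "vent_events": [list(map(float, ev)) for ev in self.vent_events],
            "labels": [[float(t), str(k)] for t, k in self.labels],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnnotationSet":
        return cls(
            neural_events=[tuple(ev) for ev in d.get("neural_events", [])],
            vent_events=[tuple(ev) for ev in d.get("vent_events", [])],
            labels=[(t, k) for t, k in d.get("labels", [])],
        )


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.json")


def write_recording(rec: Recording, path) -> None:
    """Write a recording as CSV plus a ``<name>.meta.json`` sidecar.

    ``read_recording`` inverts this to within float-formatting round-off
    (≤1e-9 per sample).
    """
    path = Path(path)
    cols = {"time": rec.eadi.times, "eadi": rec.eadi.values, "paw": rec.paw.values}
    if rec.flow is not None:
        cols["flow"] = rec.flow.values
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False, float_format="%.12g")
    meta = {
        "fs_hz": rec.fs,
        "units": {name: _CHANNEL_UNITS[name] for name in cols if name != "time"},
        "peep_cmh2o": rec.meta.get("peep_cmh2o"),
        "mode": rec.meta.get("mode"),
        "subject": rec.meta.get("subject"),
    }
    # keep any extra metadata the caller stashed
    for k, v in rec.meta.items():
        meta.setdefault(k, v)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, default=float))


def read_recording(path) -> Recording:
    """Read a recording CSV (+ sidecar) written by :func:`write_recording`.

    The time column is used only to validate uniform sampling (1% relative
    tolerance); internally samples are indexed at ``fs`` from the sidecar
    (default 62.5 Hz when no sidecar exists).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    for col in ("time", "eadi", "paw"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy()
        if not np.all(np.isfinite(vals)):
            row = int(np.flatnonzero(~np.isfinite(vals))[0])
            raise FormatError(f"{path}: non-finite value in column '{col}' at row {row}")

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    fs = float(meta.get("fs_hz") or DEFAULT_FS_HZ)

    t = df["time"].to_numpy(dtype=float)
    if t.size > 1:
        dt = np.diff(t)
        if np.any(np.abs(dt - 1.0 / fs) > 0.01 / fs):
            row = int(np.flatnonzero(np.abs(dt - 1.0 / fs) > 0.01 / fs)[0])
            raise FormatError(
                f"{path}: non-uniform sampling at row {row + 1} "
                f"(dt={dt[row]:.6g} s, expected {1.0 / fs:.6g} s)"
            )
    t0 = float(t[0]) if t.size else 0.0

    def sig(name: str) -> SampledSignal:
        return SampledSignal(name, _CHANNEL_UNITS[name], fs, df[name].to_numpy(dtype=float), t0)

    flow = sig("flow") if "flow" in df.columns else None
    return Recording(eadi=sig("eadi"), paw=sig("paw"), flow=flow, meta=meta)


def extract_analysis_window(rec: Recording, window_s: float) -> Recording:
    """Return the final ``window_s`` seconds of every channel.

    This is the stable end-of-mode analysis window (clinically the last
    5 minutes of a ventilation trial). Event times reported downstream stay
    in the original recording clock because ``t0`` is advanced by the amount
    trimmed. Recordings shorter than ``window_s`` are returned whole.
    """
    if not window_s > 0:
        raise ConfigError(f"window_s must be positive, got {window_s}")
    n_keep = min(rec.n, int(round(window_s * rec.fs)))
    start = rec.n - n_keep
    t0 = rec.t0 + start / rec.fs

    def cut(sig: Optional[SampledSignal]) -> Optional[SampledSignal]:
        if sig is None:
            return None
        return SampledSignal(sig.name, sig.unit, sig.fs, sig.values[start:].copy(), t0)

    return Recording(eadi=cut(rec.eadi), paw=cut(rec.paw), flow=cut(rec.flow), meta=dict(rec.meta))


def write_annotations(ann: AnnotationSet, path) -> None:
    Path(path).write_text(json.dumps(ann.to_dict(), indent=1))


def read_annotations(path) -> AnnotationSet:
    return AnnotationSet.from_dict(json.loads(Path(path).read_text()))
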