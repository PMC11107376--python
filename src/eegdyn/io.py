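"""Reading, writing, resampling and clock alignment of multichannel recordings.

A :class:`Recording` holds the EEG/EMG signal matrix on a uniform sample grid
together with auxiliary streams: motion-sensor event times, minute sync
pulses, and transmitter-dropout gaps.  Gaps are *annotations* — the samples
stay on the grid (as NaN runs in memory) and are never deleted, so epoch
timing is exact and the 10-ms gap rule can be applied downstream.

Two on-disk dialects are supported:

``edf``
    Plain EDF (16-bit) for the signals, written by a minimal writer in this
    module and read back through :mod:`mne`.  Events, gaps and channel roles
    travel in a JSON sidecar (``<stem>.json``) because plain EDF has no
    annotation stream.
``delimited``
    One CSV column per channel, header row of channel names, times implicit
    from the sampling rate; gaps appear as NaN runs.  Intended for small
    fixtures and interoperability.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _sig

__all__ = [
    "ChannelMeta",
    "Recording",
    "read_recording",
    "write_recording",
    "downsample",
    "align_motion",
    "ROLES",
]

ROLES = ("frontal", "temporal_A1", "temporal_V1", "emg", "reference")

#: label substrings used to resolve roles when no sidecar/config is present
_ROLE_PATTERNS = {
    "frontal": ("frontal", "pfc", "prefrontal"),
    "temporal_A1": ("a1", "auditory"),
    "temporal_V1": ("v1", "visual"),
    "emg": ("emg",),
    "reference": ("ref",),
}


@dataclass
class ChannelMeta:
    """Name, functional role and (optionally) hemisphere of one channel."""

    name: str
    role: str
    hemisphere: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown channel role {self.role!r}; expected one of {ROLES}")


@dataclass
class Recording:
    """Multichannel signal container on a uniform sample grid.

    Parameters
    ----------
    signals
        Array of shape ``(n_channels, n_samples)`` in microvolts.  Samples
        inside annotated gaps are NaN.
    fs
        Sampling rate in Hz, shared by all channels.
    channels
        Per-channel metadata, same order as the rows of ``signals``.
    motion_events
        Sorted times (s) of passive-infrared motion events, on the EEG clock
        once :func:`align_motion` has been applied.
    sync_pulses
        Sorted times (s) of the once-per-minute synchronization pulses on the
        EEG clock.
    gaps
        Sorted, non-overlapping ``(start_s, length_s)`` transmitter dropouts.
    """

    signals: np.ndarray
    fs: float
    channels: list[ChannelMeta]
    motion_events: np.ndarray = field(default_factory=lambda: np.empty(0))
    sync_pulses: np.ndarray = field(default_factory=lambda: np.empty(0))
    gaps: list[tuple[float, float]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        self.motion_events = np.asarray(self.motion_events, dtype=float)
        self.sync_pulses = np.asarray(self.sync_pulses, dtype=float)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.signals.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.signals.shape[0]} signal rows but {len(self.channels)} channel entries"
            )
        dur = self.duration_s
        for ev in (self.motion_events, self.sync_pulses):
            if ev.size and (np.any(np.diff(ev) < 0) or ev[0] < 0 or ev[-1] > dur):
                raise ValueError("event times must be sorted and within [0, duration]")
        last_end = -np.inf
        for start, length in self.gaps:
            if length <= 0 or start < 0 or start + length > dur + 1.0 / self.fs:
                raise ValueError(f"gap ({start}, {length}) outside recording")
            if start < last_end:
                raise ValueError("gaps must be sorted and non-overlapping")
            last_end = start + length

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, role: str) -> int:
        """Index of the first channel with the given role."""
        for i, ch in enumerate(self.channels):
            if ch.role == role:
                return i
        raise KeyError(f"no channel with role {role!r}")

    def get(self, role: str) -> np.ndarray:
        return self.signals[self.channel_index(role)]

    def has(self, role: str) -> bool:
        return any(ch.role == role for ch in self.channels)


# ---------------------------------------------------------------------------
# role resolution
# ---------------------------------------------------------------------------

def _resolve_roles(names: list[str], role_map: dict[str, str] | None) -> list[ChannelMeta]:
    metas = []
    for name in names:
        if role_map and name in role_map:
            metas.append(ChannelMeta(name, role_map[name]))
            continue
        low = name.lower()
        for role, pats in _ROLE_PATTERNS.items():
            if any(p in low for p in pats):
                metas.append(ChannelMeta(name, role))
                break
        else:
            raise ValueError(
                f"cannot resolve role for channel {name!r}: provide a sidecar config "
                "or a role_map argument"
            )
    return metas


def _gaps_from_nan(x: np.ndarray, fs: float) -> list[tuple[float, float]]:
    """Convert NaN runs (any channel) into gap annotations."""
    bad = np.isnan(x).any(axis=0)
    return _runs_to_gaps(bad, fs)


def _runs_to_gaps(bad: np.ndarray, fs: float) -> list[tuple[float, float]]:
    if not bad.any():
        return []
    d = np.diff(np.concatenate(([0], bad.view(np.int8), [0])))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(s / fs, (e - s) / fs) for s, e in zip(starts, ends)]


def _flatline_gaps(x: np.ndarray, fs: float, min_run: int = 4) -> list[tuple[float, float]]:
    """Detect the flat-line dropout sentinel: identical consecutive samples on
    every channel for at least ``min_run`` samples."""
    same = np.ones(x.shape[1], dtype=bool)
    same[1:] = (np.diff(x, axis=1) == 0).all(axis=0)
    same[0] = False
    # a run of k identical diffs marks k+1 samples; require min_run samples
    bad = np.zeros(x.shape[1], dtype=bool)
    d = np.diff(np.concatenate(([0], same.view(np.int8), [0])))
    for s, e in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
        if e - s + 1 >= min_run:
            bad[s - 1 : e] = True
    return _runs_to_gaps(bad, fs)


# ---------------------------------------------------------------------------
# minimal EDF writer (plain EDF, 16-bit)
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(path: Path, rec: Recording) -> None:
    """Write a plain EDF file: one data record per second, int16 samples.

    Requires an integer sampling rate.  NaN (gap) samples are written as the
    flat-line sentinel 0 µV; gap annotations travel in the JSON sidecar.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    nchan = len(rec.channels)
    n_records = math.ceil(rec.n_samples / fs)
    n_total = n_records * fs

    data = np.nan_to_num(rec.signals, nan=0.0)
    if rec.n_samples < n_total:  # pad the trailing partial record
        pad = np.zeros((nchan, n_total - rec.n_samples))
        data = np.concatenate([data, pad], axis=1)

    phys_min = np.floor(np.minimum(data.min(axis=1), -1.0))
    phys_max = np.ceil(np.maximum(data.max(axis=1), 1.0))
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((data - phys_min[:, None]) * scale[:, None] + dig_min).astype("<i2")

    header_bytes = 256 * (1 + nchan)
    with open(path, "wb") as f:
        f.write(_edf_field("0", 8))
        f.write(_edf_field("X X X X", 80))            # patient id
        f.write(_edf_field("Startdate X X X X", 80))  # recording id
        f.write(_edf_field("01.01.00", 8))
        f.write(_edf_field("00.00.00", 8))
        f.write(_edf_field(header_bytes, 8))
        f.write(_edf_field("", 44))
        f.write(_edf_field(n_records, 8))
        f.write(_edf_field(1, 8))                     # record duration, s
        f.write(_edf_field(nchan, 4))
        for ch in rec.channels:
            f.write(_edf_field(ch.name, 16))
        for _ in rec.channels:
            f.write(_edf_field("", 80))               # transducer
        for _ in rec.channels:
            f.write(_edf_field("uV", 8))
        for v in phys_min:
            f.write(_edf_field(f"{v:g}", 8))
        for v in phys_max:
            f.write(_edf_field(f"{v:g}", 8))
        for _ in rec.channels:
            f.write(_edf_field(dig_min, 8))
        for _ in rec.channels:
            f.write(_edf_field(dig_max, 8))
        for _ in rec.channels:
            f.write(_edf_field("", 80))               # prefiltering
        for _ in rec.channels:
            f.write(_edf_field(fs, 8))
        for _ in rec.channels:
            f.write(_edf_field("", 32))
        # data records: per record, per channel, fs int16 samples
        blocks = digital.reshape(nchan, n_records, fs)
        f.write(np.ascontiguousarray(blocks.transpose(1, 0, 2)).tobytes())


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(path: str | Path, rec: Recording, dialect: str = "edf") -> Path:
    """Write a recording plus its JSON sidecar; returns the signal file path."""
    path = Path(path)
    if dialect == "edf":
        _write_edf(path, rec)
    elif dialect == "delimited":
        df = pd.DataFrame(rec.signals.T, columns=[ch.name for ch in rec.channels])
        df.to_csv(path, index=False, float_format="%.6f", na_rep="nan")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    sidecar = {
        "fs": rec.fs,
        "channel_roles": {ch.name: ch.role for ch in rec.channels},
        "motion_events": np.asarray(rec.motion_events).tolist(),
        "sync_pulses": np.asarray(rec.sync_pulses).tolist(),
        "gaps": [[float(s), float(l)] for s, l in rec.gaps],
        "meta": _jsonable(rec.meta),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def read_recording(
    path: str | Path,
    dialect: str | None = None,
    role_map: dict[str, str] | None = None,
) -> Recording:
    """Read a recording from EDF or delimited text.

    The dialect is inferred from the file extension when not given.  Channel
    roles come, in order of precedence, from the JSON sidecar, ``role_map``,
    or label-pattern matching; unresolvable labels raise ``ValueError``.
    Missing-sample runs (NaN runs, or the all-channel flat-line sentinel in
    EDF) are converted to gap annotations and NaN-ed in memory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "edf" if path.suffix.lower() == ".edf" else "delimited"

    sidecar = None
    sc_path = _sidecar_path(path)
    if sc_path.exists() and sc_path != path:
        sidecar = json.loads(sc_path.read_text())

    if dialect == "edf":
        import mne

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        names = list(raw.ch_names)
        data = raw.get_data() * 1e6  # mne converts µV dimension to volts
        fs = float(raw.info["sfreq"])
    elif dialect == "delimited":
        df = pd.read_csv(path)
        names = [str(c) for c in df.columns]
        data = df.to_numpy(dtype=float).T
        if sidecar is None or "fs" not in sidecar:
            raise ValueError("delimited dialect needs a sidecar JSON with the sampling rate")
        fs = float(sidecar["fs"])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    roles = dict(sidecar.get("channel_roles", {})) if sidecar else {}
    if role_map:
        roles.update(role_map)
    metas = _resolve_roles(names, roles or None)

    if sidecar and "gaps" in sidecar:
        gaps = [(float(s), float(l)) for s, l in sidecar["gaps"]]
    else:
        gaps = _gaps_from_nan(data, fs)
        if not gaps and dialect == "edf":
            gaps = _flatline_gaps(data, fs)
    # NaN out annotated gap samples so downstream code cannot use them silently
    for start, length in gaps:
        i0 = int(round(start * fs))
        i1 = int(round((start + length) * fs))
        data[:, i0:i1] = np.nan

    rec = Recording(
        signals=data,
        fs=fs,
        channels=metas,
        motion_events=np.asarray(sidecar.get("motion_events", [])) if sidecar else np.empty(0),
        sync_pulses=np.asarray(sidecar.get("sync_pulses", [])) if sidecar else np.empty(0),
        gaps=gaps,
        meta=dict(sidecar.get("meta", {})) if sidecar else {},
    )
    return rec


# ---------------------------------------------------------------------------
# resampling and clock alignment
# ---------------------------------------------------------------------------

def downsample(rec: Recording, target_fs: float = 1000.0) -> Recording:
    """Anti-alias filter and resample all channels to ``target_fs``.

    Polyphase resampling via :func:`scipy.signal.resample_poly`.  Gap and
    event times are in seconds and are unchanged; gap samples are NaN-ed
    again on the new grid (NaNs are linearly bridged before filtering so the
    anti-alias filter does not smear them over clean data).
    """
    if target_fs > rec.fs:
        raise ValueError(f"target_fs {target_fs} exceeds recording fs {rec.fs}")
    if abs(target_fs - rec.fs) < 1e-12:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(10**6)
    up, down = frac.numerator, frac.denominator

    filled = rec.signals.copy()
    for row in filled:
        nan = np.isnan(row)
        if nan.any():
            idx = np.arange(row.size)
            row[nan] = np.interp(idx[nan], idx[~nan], row[~nan])
    out = _sig.resample_poly(filled, up, down, axis=1)
    for start, length in rec.gaps:
        i0 = int(round(start * target_fs))
        i1 = max(i0 + 1, int(round((start + length) * target_fs)))
        out[:, i0 : min(i1, out.shape[1])] = np.nan
    return replace(rec, signals=out, fs=float(target_fs))


def align_motion(
    rec: Recording,
    motion_pulses: np.ndarray | None = None,
) -> tuple[Recording, float]:
    """Map motion-sensor event times onto the EEG clock.

    The motion acquisition system runs on its own clock; both systems see the
    same once-per-minute digital pulses.  A piecewise-linear map through the
    pulse pairs ``(motion_pulses[i], rec.sync_pulses[i])`` (linear
    extrapolation beyond the first/last pair) converts event times.  Returns
    the corrected recording and the maximum absolute correction (s) applied,
    a residual-drift diagnostic.

    When ``motion_pulses`` is None the two clocks are assumed identical and
    the recording is returned unchanged (drift 0).
    """
    if motion_pulses is None:
        return rec, 0.0
    motion_pulses = np.asarray(motion_pulses, dtype=float)
    sync = np.asarray(rec.sync_pulses, dtype=float)
    if sync.size < 2 or motion_pulses.size < 2:
        raise ValueError("alignment needs at least 2 sync pulses on each clock")
    if np.any(np.diff(motion_pulses) <= 0):
        raise ValueError("motion pulse times must be strictly increasing")
    if motion_pulses.size != sync.size:
        raise ValueError("pulse counts differ between clocks")

    ev = np.asarray(rec.motion_events, dtype=float)
    mapped = np.interp(ev, motion_pulses, sync)
    # linear extrapolation outside the pulse span
    lo_slope = (sync[1] - sync[0]) / (motion_pulses[1] - motion_pulses[0])
    hi_slope = (sync[-1] - sync[-2]) / (motion_pulses[-1] - motion_pulses[-2])
    below = ev < motion_pulses[0]
    above = ev > motion_pulses[-1]
    mapped[below] = sync[0] + (ev[below] - motion_pulses[0]) * lo_slope
    mapped[above] = sync[-1] + (ev[above] - motion_pulses[-1]) * hi_slope
    mapped = np.clip(mapped, 0.0, rec.duration_s)
    drift = float(np.max(np.abs(mapped - ev))) if ev.size else 0.0
    return replace(rec, motion_events=np.sort(mapped)), drift
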