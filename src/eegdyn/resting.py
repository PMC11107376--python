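"""Vigilance scoring of 5-s epochs and extraction of resting-state segments.

The scoring heuristics operationalize rodent "resting state" as wakeful
inactivity: an epoch counts as rest when the frontal EEG shows no
slow-wave-sleep signature (no high-amplitude < 4 Hz waves), there is no
motor activity (no motion-sensor event and no elevated EMG), and the epoch
does not immediately follow sleep (a guard against scoring REM sleep as
rest).  The amplitude criteria are expressed relative to recording-wide
medians so they adapt to per-animal signal scale; the multipliers are
configurable (:class:`ScoringThresholds`).

Signal-quality rules follow the epoch conventions of wireless rodent EEG:
epochs containing a transmitter gap longer than 10 ms are excluded as
signal-loss artifacts, shorter gaps are bridged by linear interpolation, and
rest epochs with high-amplitude deflections, high-frequency noise, or
abundant brief spikes are rejected as artifacts.  A recording is included in
analysis only if it retains at least 80 s of resting-state signal and loses
no more than 50% of its original resting data to rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .io import Recording

__all__ = [
    "ScoringThresholds",
    "EpochLabels",
    "RestingSegmentSet",
    "score_epochs",
    "apply_gap_rules",
    "reject_artifacts",
    "extract_resting",
    "resting_segments_signal",
]

EPOCH_S = 5.0
LABELS = ("rest", "sws", "active", "post_sleep", "artifact", "signal_loss")

MIN_REST_S = 80.0       #: a-priori minimum resting-state signal per recording
MAX_REJECT_FRAC = 0.5   #: a-priori maximum rejected fraction of resting data
GAP_LIMIT_S = 0.010     #: gaps longer than this exclude the epoch


@dataclass(frozen=True)
class ScoringThresholds:
    """Multipliers on recording-wide medians / robust SD for the heuristics."""

    k_delta: float = 3.0   #: sws when delta envelope > k_delta x median
    k_emg: float = 2.5     #: active when epoch EMG RMS > k_emg x median RMS
    k_amp: float = 6.0     #: artifact when peak |x| > k_amp x robust SD
    k_hf: float = 0.5      #: artifact when 70-99 Hz power fraction > k_hf
    k_spk: int = 3         #: artifact when more than k_spk brief spikes
    spike_sd: float = 5.0  #: spike excursion threshold, robust SDs


@dataclass
class EpochLabels:
    """Per-epoch vigilance/quality labels and diagnostics."""

    labels: list[str]
    diagnostics: pd.DataFrame  #: delta_amp, emg_rms, motion_count, max_gap_ms per epoch
    epoch_length_s: float = EPOCH_S
    n_rejected_rest: int = 0   #: rest epochs lost to artifact/signal-loss rules

    def __post_init__(self) -> None:
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels {bad}")
        for i in range(1, len(self.labels)):
            if self.labels[i] == "rest" and self.labels[i - 1] == "sws":
                raise ValueError("invariant violated: rest directly follows sws")

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    def counts(self) -> dict[str, int]:
        return {lab: self.labels.count(lab) for lab in LABELS}

    def to_frame(self) -> pd.DataFrame:
        df = self.diagnostics.copy()
        df.insert(0, "label", self.labels)
        df.insert(0, "start_s", np.arange(self.n_epochs) * self.epoch_length_s)
        df.insert(0, "epoch", np.arange(self.n_epochs))
        return df


@dataclass
class RestingSegmentSet:
    """Maximal contiguous runs of clean resting epochs."""

    segments: list[tuple[float, float]]  #: (start_s, end_s), half-open
    total_s: float
    included: bool
    rejected_fraction: float = 0.0

    @property
    def n_epochs(self) -> int:
        return int(round(self.total_s / EPOCH_S))

    def to_bed(self, name: str = "rest") -> str:
        """BED-like half-open intervals in seconds (0-based starts)."""
        return "".join(f"{name}\t{s:g}\t{e:g}\n" for s, e in self.segments)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _fill_nan(x: np.ndarray) -> np.ndarray:
    nan = np.isnan(x)
    if not nan.any():
        return x
    out = x.copy()
    idx = np.arange(x.size)
    if nan.all():
        return np.zeros_like(x)
    out[nan] = np.interp(idx[nan], idx[~nan], out[~nan])
    return out


def _lowpass(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    sos = _sig.butter(4, cutoff, btype="low", fs=fs, output="sos")
    return _sig.sosfiltfilt(sos, x)


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    sos = _sig.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    return _sig.sosfiltfilt(sos, x)


def score_epochs(rec: Recording, thresholds: ScoringThresholds = ScoringThresholds()) -> EpochLabels:
    """Score every 5-s epoch as rest / sws / active / post_sleep.

    The frontal channel is low-pass filtered at 70 Hz; an epoch is ``sws``
    when its mean delta-band (0.5–4 Hz) envelope amplitude exceeds
    ``k_delta`` times the recording-wide median, ``active`` when a motion
    event falls inside it or its EMG RMS exceeds ``k_emg`` times the
    recording-wide median, and ``rest`` otherwise.  Any rest epoch directly
    following an sws epoch is relabeled ``post_sleep``.
    """
    if rec.fs < 200:
        raise ValueError("scoring requires fs >= 200 Hz")
    for role in ("frontal", "emg"):
        if not rec.has(role):
            raise ValueError(f"scoring requires a {role} channel")
    ep = int(round(EPOCH_S * rec.fs))
    n_ep = rec.n_samples // ep
    if n_ep < 1:
        raise ValueError("recording shorter than one 5-s epoch")

    frontal = _fill_nan(rec.get("frontal"))
    frontal = _lowpass(frontal, rec.fs, min(70.0, 0.45 * rec.fs))
    delta = _bandpass(frontal, rec.fs, 0.5, 4.0)
    delta_env = np.abs(_sig.hilbert(delta))
    emg = _fill_nan(rec.get("emg"))

    used = n_ep * ep
    delta_amp = delta_env[:used].reshape(n_ep, ep).mean(axis=1)
    emg_rms = np.sqrt((emg[:used] ** 2).reshape(n_ep, ep).mean(axis=1))
    motion_count = np.histogram(rec.motion_events, bins=n_ep,
                                range=(0, n_ep * EPOCH_S))[0]
    max_gap_ms = np.zeros(n_ep)
    for start, length in rec.gaps:
        first = int(start // EPOCH_S)
        last = int((start + length - 1e-12) // EPOCH_S)
        for i in range(first, min(last, n_ep - 1) + 1):
            seg_lo = max(start, i * EPOCH_S)
            seg_hi = min(start + length, (i + 1) * EPOCH_S)
            max_gap_ms[i] = max(max_gap_ms[i], 1000.0 * (seg_hi - seg_lo))

    # baseline = lower quartile of epoch statistics: equivalent to the median
    # in rest-dominated recordings but robust when sleep or movement occupies
    # more than half the epochs (the median would then sit on the elevated
    # state and the thresholds would never trigger)
    delta_med = np.quantile(delta_amp, 0.25)
    emg_med = np.quantile(emg_rms, 0.25)
    labels = []
    for i in range(n_ep):
        if delta_amp[i] > thresholds.k_delta * delta_med:
            labels.append("sws")
        elif motion_count[i] > 0 or emg_rms[i] > thresholds.k_emg * emg_med:
            labels.append("active")
        else:
            labels.append("rest")
    for i in range(1, n_ep):
        if labels[i] == "rest" and labels[i - 1] == "sws":
            labels[i] = "post_sleep"

    diag = pd.DataFrame({
        "delta_amp": delta_amp,
        "emg_rms": emg_rms,
        "motion_count": motion_count,
        "max_gap_ms": max_gap_ms,
    })
    return EpochLabels(labels=labels, diagnostics=diag)


# ---------------------------------------------------------------------------
# gap and artifact rules
# ---------------------------------------------------------------------------

def apply_gap_rules(rec: Recording, labels: EpochLabels) -> tuple[Recording, EpochLabels]:
    """Exclude epochs with gaps > 10 ms; bridge shorter gaps linearly.

    "More than 10 ms" is read strictly: a gap of exactly 10 ms is
    interpolated and kept.  Interpolation draws a straight line from the last
    sample before to the first sample after the gap; a gap touching the
    recording boundary has no flanking sample, so its epoch is excluded
    instead.
    """
    fs = rec.fs
    new_labels = list(labels.labels)
    signals = rec.signals.copy()
    n = signals.shape[1]
    n_ep = labels.n_epochs
    rejected = labels.n_rejected_rest

    def mark_loss(start: float, length: float) -> None:
        nonlocal rejected
        first = int(start // EPOCH_S)
        last = int((start + length - 1e-12) // EPOCH_S)
        for i in range(first, min(last, n_ep - 1) + 1):
            if new_labels[i] == "rest":
                rejected += 1
            if new_labels[i] != "signal_loss":
                new_labels[i] = "signal_loss"

    for start, length in rec.gaps:
        i0 = int(round(start * fs))
        i1 = max(i0 + 1, int(round((start + length) * fs)))
        if length > GAP_LIMIT_S + 1e-12:
            mark_loss(start, length)
            continue
        if i0 <= 0 or i1 >= n:  # boundary gap: no flanking sample
            mark_loss(start, length)
            continue
        left = signals[:, i0 - 1]
        right = signals[:, i1]
        if np.isnan(left).any() or np.isnan(right).any():
            mark_loss(start, length)
            continue
        w = (np.arange(1, i1 - i0 + 1)) / (i1 - i0 + 1)
        signals[:, i0:i1] = left[:, None] + (right - left)[:, None] * w[None, :]

    out = replace(rec, signals=signals)
    new = EpochLabels(labels=new_labels, diagnostics=labels.diagnostics,
                      n_rejected_rest=rejected)
    return out, new


def reject_artifacts(rec: Recording, labels: EpochLabels,
                     thresholds: ScoringThresholds = ScoringThresholds()) -> EpochLabels:
    """Relabel rest epochs as ``artifact`` on amplitude / HF-noise / spike rules.

    A rest epoch is rejected when, on any EEG channel: the peak absolute
    amplitude exceeds ``k_amp`` robust SDs (1.4826 × MAD, recording-wide); or
    the 70–99 Hz fraction of 1–99 Hz power exceeds ``k_hf``; or it contains
    more than ``k_spk`` threshold excursions shorter than 5 ms.
    """
    fs = rec.fs
    ep = int(round(EPOCH_S * fs))
    n_ep = labels.n_epochs
    eeg_rows = [i for i, ch in enumerate(rec.channels)
                if ch.role in ("frontal", "temporal_A1", "temporal_V1")]
    new_labels = list(labels.labels)
    rejected = labels.n_rejected_rest

    hf_ok = fs / 2 > 70.0
    for row in eeg_rows:
        x = _fill_nan(rec.signals[row])
        med = np.median(x)
        rsd = 1.4826 * np.median(np.abs(x - med))
        if rsd == 0:
            rsd = x.std() or 1.0
        for i in range(n_ep):
            if new_labels[i] != "rest":
                continue
            seg = x[i * ep:(i + 1) * ep]
            dev = np.abs(seg - med)
            if dev.max() > thresholds.k_amp * rsd:
                new_labels[i] = "artifact"
                rejected += 1
                continue
            if hf_ok:
                freqs = np.fft.rfftfreq(seg.size, 1 / fs)
                p = np.abs(np.fft.rfft(seg - seg.mean()) / seg.size) ** 2
                tot = p[(freqs >= 1) & (freqs <= 99)].sum()
                hf = p[(freqs >= 70) & (freqs <= 99)].sum()
                if tot > 0 and hf / tot > thresholds.k_hf:
                    new_labels[i] = "artifact"
                    rejected += 1
                    continue
            # brief spikes: excursions above spike_sd robust SDs, < 5 ms long
            over = dev > thresholds.spike_sd * rsd
            if over.any():
                d = np.diff(np.concatenate(([0], over.view(np.int8), [0])))
                runs = np.flatnonzero(d == -1) - np.flatnonzero(d == 1)
                n_spikes = int((runs < 0.005 * fs).sum())
                if n_spikes > thresholds.k_spk:
                    new_labels[i] = "artifact"
                    rejected += 1
    return EpochLabels(labels=new_labels, diagnostics=labels.diagnostics,
                       n_rejected_rest=rejected)


# ---------------------------------------------------------------------------
# resting-segment extraction
# ---------------------------------------------------------------------------

def extract_resting(labels: EpochLabels) -> RestingSegmentSet:
    """Maximal contiguous runs of rest epochs, with the inclusion flag.

    ``included`` requires at least 80 s of resting signal and a rejected
    fraction (rest epochs lost to the gap/artifact rules, relative to the
    originally resting data) of at most 50%.
    """
    segments: list[tuple[float, float]] = []
    start = None
    for i, lab in enumerate(labels.labels + ["_end"]):
        if lab == "rest":
            if start is None:
                start = i
        elif start is not None:
            segments.append((start * EPOCH_S, i * EPOCH_S))
            start = None
    total = sum(e - s for s, e in segments)
    n_rest = int(round(total / EPOCH_S))
    denom = n_rest + labels.n_rejected_rest
    frac = labels.n_rejected_rest / denom if denom else 1.0
    included = total >= MIN_REST_S and frac <= MAX_REJECT_FRAC
    return RestingSegmentSet(segments=segments, total_s=float(total),
                             included=included, rejected_fraction=float(frac))


def resting_segments_signal(rec: Recording, segset: RestingSegmentSet,
                            role: str | None = None) -> list[np.ndarray]:
    """Raw-signal arrays for each resting segment.

    ``role`` picks one channel; ``"temporal"`` averages the A1 and V1
    channels (the temporal-cortex signal); None returns the full channel
    matrix per segment.
    """
    if role == "temporal":
        rows = [rec.channel_index("temporal_A1"), rec.channel_index("temporal_V1")]
        data = rec.signals[rows].mean(axis=0)
    elif role is not None:
        data = rec.get(role)
    else:
        data = rec.signals
    out = []
    for s, e in segset.segments:
        i0, i1 = int(round(s * rec.fs)), int(round(e * rec.fs))
        out.append(data[..., i0:i1])
    return out
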