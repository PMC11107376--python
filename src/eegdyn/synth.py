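"""Synthetic rodent EEG with planted ground truth.

Every downstream stage of the pipeline is verified against recordings whose
relevant properties are known by construction:

* band-limited oscillations whose amplitude envelopes have a controllable
  DFA (Hurst) exponent — fractional Gaussian noise, synthesized with its
  exact autocovariance by circulant embedding, passed through a lognormal
  transform.  The multiplicative (lognormal) envelope is deliberate: on a
  multiplicative envelope the fluctuation of the amplitude-normalized
  profile is independent of the window amplitude, so the planted balanced
  state (κ = 0) measures fEI ≈ 1.  An additive-offset envelope would bias
  fEI upward, because dividing a level-independent fluctuation by the window
  amplitude manufactures a negative correlation.
* controllable window-amplitude↔fluctuation coupling κ: within consecutive
  non-overlapping 5-s blocks the demeaned envelope deviations are scaled by
  exp(−κ·z), where z is the z-scored log block amplitude.  κ = 0 leaves the
  envelope untouched (balanced, fEI ≈ 1); κ > 0 plants an
  excitation-dominated signal (fEI > 1); κ < 0 inhibition-dominated
  (fEI < 1).  Block mean amplitudes are unchanged.
* a scripted wake/sleep/movement schedule, transmitter-dropout gaps,
  high-amplitude artifact transients, and genotype presets with group-level
  spectral contrasts.

Identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import ChannelMeta, Recording, write_recording

__all__ = [
    "SyntheticSpec",
    "GenotypePreset",
    "GroundTruth",
    "PRESETS",
    "fractional_gaussian_noise",
    "generate_envelope",
    "generate_coupled_oscillation",
    "generate_recording",
    "generate_cohort",
    "write_cohort",
]

EPOCH_S = 5.0
STATES = ("rest", "sws", "active")

#: canonical frequency bands (Hz) used to address carriers in presets
BANDS = {"delta": (0.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0),
         "beta": (13.0, 30.0), "gamma": (30.0, 100.0)}


def band_of(f: float) -> str:
    for name, (lo, hi) in BANDS.items():
        if lo <= f < hi:
            return name
    raise ValueError(f"frequency {f} Hz outside the defined bands")


# ---------------------------------------------------------------------------
# fractional Gaussian noise
# ---------------------------------------------------------------------------

def fractional_gaussian_noise(hurst: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance fGn with exact target autocovariance.

    Circulant embedding (Davies–Harte): the circular extension of the fGn
    autocovariance is diagonalized by the FFT; if the embedding is
    non-negative-definite (it is for fGn at these sizes, but the guard stays)
    fall back to spectral synthesis with the fGn power spectrum.
    """
    if not 0 < hurst < 1:
        raise ValueError(f"hurst must be in (0, 1), got {hurst}")
    if n < 2:
        raise ValueError("need at least 2 samples")
    k = np.arange(n, dtype=float)
    gamma = 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst) + np.abs(k - 1) ** (2 * hurst))
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    m = row.size  # 2(n-1)
    lam = np.fft.fft(row).real
    if lam.min() < -1e-9 * lam.max():
        # spectral fallback: shape white noise by the fGn amplitude spectrum
        freqs = np.fft.rfftfreq(2 * n)[1:]
        amp = freqs ** (0.5 - hurst)
        w = rng.standard_normal(2 * n)
        W = np.fft.rfft(w)
        W[1:] *= amp
        W[0] = 0
        x = np.fft.irfft(W, 2 * n)[:n]
        return x / x.std()
    lam = np.maximum(lam, 0.0)
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = np.fft.fft(np.sqrt(lam / m) * z).real[:n]
    return x


def generate_envelope(
    hurst: float,
    n_samples: int,
    fs: float,
    seed: int,
    sigma_log: float = 0.3,
) -> np.ndarray:
    """Strictly positive amplitude envelope with DFA exponent ≈ ``hurst``.

    exp(sigma_log · fGn_H), normalized to unit mean.  The lognormal transform
    preserves the scaling exponent (measured bias < 0.02 across H in
    0.55–0.85) and gives the envelope the multiplicative structure required
    for a balanced fEI calibration (see the module docstring).
    """
    if not 0 < hurst < 1:
        raise ValueError(f"hurst must be in (0, 1), got {hurst}")
    if n_samples < 2 ** 10:
        raise ValueError(f"n_samples must be at least 2^10, got {n_samples}")
    rng = np.random.default_rng(seed)
    g = fractional_gaussian_noise(hurst, n_samples, rng)
    g = (g - g.mean()) / g.std()
    env = np.exp(sigma_log * g)
    return env / env.mean()


def apply_coupling(env: np.ndarray, fs: float, kappa: float, block_s: float = EPOCH_S) -> np.ndarray:
    """Plant amplitude↔fluctuation coupling κ into an envelope.

    In consecutive non-overlapping blocks the demeaned deviations are scaled
    by exp(−κ·z), z being the z-scored log block-mean amplitude; block means
    are untouched, so the quantity fEI correlates (window fluctuation vs
    window amplitude) is set directly while the amplitude series keeps its
    planted LRTC.
    """
    if abs(kappa) > 3:
        raise ValueError(f"|kappa| = {abs(kappa)} too large; envelope would degenerate")
    if kappa == 0:
        return env.copy()
    b = int(round(block_s * fs))
    n_b = env.size // b
    if n_b < 2:
        raise ValueError("envelope shorter than two coupling blocks")
    out = env.copy()
    head = out[: n_b * b].reshape(n_b, b)
    means = head.mean(axis=1)
    lz = np.log(means)
    sd = lz.std()
    z = (lz - lz.mean()) / sd if sd > 0 else np.zeros_like(lz)
    gain = np.exp(-kappa * z)
    head[:] = means[:, None] + (head - means[:, None]) * gain[:, None]
    np.clip(out, 1e-9, None, out=out)
    return out


def one_over_f_noise(n: int, fs: float, exponent: float, sigma: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Broadband background with power spectrum ∝ 1/f^exponent, SD = sigma (µV)."""
    w = rng.standard_normal(n)
    W = np.fft.rfft(w)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2)
    W *= shape
    x = np.fft.irfft(W, n)
    s = x.std()
    return x * (sigma / s) if s > 0 else x


# ---------------------------------------------------------------------------
# spec and presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of one simulated recording.

    Defaults emulate a five-minute rodent home-cage segment at the analysis
    rate of 1000 Hz with a weak resting delta rhythm, a theta rhythm and one
    gamma oscillation; amplitudes in µV sit on a 10-µV 1/f background.
    """

    duration_s: float = 300.0
    fs: float = 1000.0
    carrier_freqs: tuple[float, ...] = (2.5, 6.0, 40.0)
    carrier_amps: tuple[float, ...] = (4.0, 8.0, 20.0)
    hurst: tuple[float, ...] = (0.60, 0.70, 0.75)
    coupling_kappa: tuple[float, ...] = (0.0, 0.0, 0.0)
    state_schedule: tuple[tuple[str, float], ...] = (("rest", 300.0),)
    gap_rate: float = 0.0           #: gaps per minute
    gap_length_ms: tuple[float, float] = (2.0, 50.0)  #: log-uniform range
    artifact_rate: float = 0.0      #: high-amplitude transients per minute
    noise_floor: tuple[float, float] = (1.0, 10.0)    #: (1/f exponent, SD µV)
    sws_delta_freq: float = 2.5
    sws_delta_amp: float = 50.0
    emg_sigma: float = 5.0
    emg_active_gain: float = 5.0
    motion_rate_active: float = 20.0  #: PIR events per minute while active
    explicit_gaps: tuple[tuple[float, float], ...] = ()      #: (start_s, length_s)
    explicit_artifacts: tuple[float, ...] = ()               #: start_s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs < 4 * max(self.carrier_freqs):
            raise ValueError("fs must be at least 4x the highest carrier frequency")
        if not (len(self.carrier_freqs) == len(self.carrier_amps)
                == len(self.hurst) == len(self.coupling_kappa)):
            raise ValueError("per-carrier tuples must have equal length")
        for h in self.hurst:
            if not 0 < h < 1:
                raise ValueError(f"hurst must be in (0, 1), got {h}")
        total = sum(d for _, d in self.state_schedule)
        if abs(total - self.duration_s) > 1e-9:
            raise ValueError(
                f"schedule durations sum to {total}, expected duration_s={self.duration_s}")
        for s, _ in self.state_schedule:
            if s not in STATES:
                raise ValueError(f"unknown state {s!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass(frozen=True)
class GenotypePreset:
    """Group-level multipliers planted on top of a base spec, per band.

    ``power``: carrier power multipliers; ``hurst_shift``: additive shifts of
    the envelope Hurst exponent; ``kappa``: absolute coupling values;
    ``broadband_power``: multiplier on the 1/f background power.
    """

    name: str
    power: dict[str, float] = field(default_factory=dict)
    hurst_shift: dict[str, float] = field(default_factory=dict)
    kappa: dict[str, float] = field(default_factory=dict)
    broadband_power: float = 1.0

    def apply(self, spec: SyntheticSpec) -> SyntheticSpec:
        amps, hs, ks = [], [], []
        for f, a, h, k in zip(spec.carrier_freqs, spec.carrier_amps,
                              spec.hurst, spec.coupling_kappa):
            b = band_of(f)
            amps.append(a * np.sqrt(self.power.get(b, 1.0)))
            hs.append(min(0.95, h + self.hurst_shift.get(b, 0.0)))
            ks.append(self.kappa.get(b, k))
        exp_, sd = spec.noise_floor
        return replace(
            spec,
            carrier_amps=tuple(amps),
            hurst=tuple(hs),
            coupling_kappa=tuple(ks),
            noise_floor=(exp_, sd * float(np.sqrt(self.broadband_power))),
        )


#: Genotype presets plant the reported directions of group differences:
#: knockouts show elevated power (broadband, strongest in gamma), higher
#: gamma LRTC, and inhibition-shifted gamma fEI.  Pharmacological presets
#: mirror a GABA-potentiator-like profile against saline.
PRESETS: dict[str, GenotypePreset] = {
    "WT": GenotypePreset("WT"),
    "KO": GenotypePreset(
        "KO",
        power={"gamma": 1.6},
        hurst_shift={"gamma": 0.08},
        kappa={"gamma": -0.3},
        broadband_power=1.4,
    ),
    "saline": GenotypePreset("saline"),
    "clz_low": GenotypePreset(
        "clz_low", power={"delta": 0.85}, hurst_shift={"gamma": 0.03},
        kappa={"gamma": -0.1},
    ),
    "clz_high": GenotypePreset(
        "clz_high", power={"delta": 0.6}, hurst_shift={"gamma": 0.08},
        kappa={"gamma": -0.3},
    ),
    "mpep": GenotypePreset("mpep"),
}


# ---------------------------------------------------------------------------
# recording generation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Sidecar truth for one generated recording."""

    epoch_states: list[str]             #: scheduled state per 5-s epoch
    artifact_epochs: list[int]          #: epoch indices containing a transient
    gaps: list[tuple[float, float]]     #: (start_s, length_s)
    carrier_freqs: list[float]
    hurst: list[float]
    kappa: list[float]
    seed: int
    preset: str = ""

    def expected_labels(self) -> list[str]:
        """Labels an ideal scorer should produce: scheduled states with the
        no-rest-after-sleep rule, gap (>10 ms) and artifact overrides."""
        labels = list(self.epoch_states)
        for i in range(1, len(labels)):
            if labels[i] == "rest" and labels[i - 1] == "sws":
                labels[i] = "post_sleep"
        for start, length in self.gaps:
            if length > 0.010 + 1e-12:
                for ep in range(int(start // EPOCH_S),
                                int((start + length - 1e-12) // EPOCH_S) + 1):
                    if ep < len(labels):
                        labels[ep] = "signal_loss"
        for ep in self.artifact_epochs:
            if ep < len(labels) and labels[ep] == "rest":
                labels[ep] = "artifact"
        return labels

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["gaps"] = [[float(a), float(b)] for a, b in self.gaps]
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["gaps"] = [tuple(g) for g in d["gaps"]]
        return cls(**d)


def _carrier_seed(seed: int, i: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(i,)).generate_state(1)[0]
               % (2 ** 31))


def generate_coupled_oscillation(spec: SyntheticSpec, carrier_index: int) -> np.ndarray:
    """One planted oscillation: carrier × coupled lognormal envelope, on a
    1/f background.  Deterministic in (spec.seed, carrier_index)."""
    f = spec.carrier_freqs[carrier_index]
    amp = spec.carrier_amps[carrier_index]
    n = spec.n_samples
    sub = _carrier_seed(spec.seed, carrier_index)
    env = generate_envelope(spec.hurst[carrier_index], n, spec.fs, sub)
    env = apply_coupling(env, spec.fs, spec.coupling_kappa[carrier_index])
    rng = np.random.default_rng(sub + 1)
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n) / spec.fs
    sig = amp * env * np.cos(2 * np.pi * f * t + phase)
    exp_, sd = spec.noise_floor
    sig += one_over_f_noise(n, spec.fs, exp_, sd, np.random.default_rng(sub + 2))
    return sig


def _ramped_mask(blocks: list[tuple[int, int]], n: int, fs: float,
                 ramp_s: float = 0.5) -> np.ndarray:
    """0/1 state mask with raised-cosine onsets/offsets to avoid clicks."""
    mask = np.zeros(n)
    r = int(round(ramp_s * fs))
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(r) / r)) if r > 0 else None
    for i0, i1 in blocks:
        mask[i0:i1] = 1.0
        if ramp is not None:
            a = min(r, i1 - i0)
            mask[i0:i0 + a] = np.minimum(mask[i0:i0 + a], ramp[:a])
            mask[i1 - a:i1] = np.minimum(mask[i1 - a:i1], ramp[:a][::-1])
    return mask


def generate_recording(
    spec: SyntheticSpec,
    preset: GenotypePreset | None = None,
) -> tuple[Recording, GroundTruth]:
    """Simulate a multichannel recording with ground-truth annotations.

    Channels: one frontal EEG, two temporal EEG (above auditory and visual
    cortex; they share the planted oscillations, as a common source seen by
    both electrodes, plus independent background noise), one EMG.  During
    ``sws`` blocks the frontal channel carries high-amplitude slow (< 4 Hz)
    waves; during ``active`` blocks the EMG RMS is elevated and PIR motion
    events are emitted.  Transmitter gaps (NaN runs on every channel) and
    200-ms half-sine transients at 10× the channel SD are injected at the
    configured rates.
    """
    if preset is not None:
        spec = preset.apply(spec)
    n = spec.n_samples
    fs = spec.fs
    master = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed,
                                                          spawn_key=(999,)))

    # planted oscillations (shared across EEG channels, like a common source)
    carriers = np.zeros(n)
    for i in range(len(spec.carrier_freqs)):
        f = spec.carrier_freqs[i]
        amp = spec.carrier_amps[i]
        sub = _carrier_seed(spec.seed, i)
        env = generate_envelope(spec.hurst[i], n, fs, sub)
        env = apply_coupling(env, fs, spec.coupling_kappa[i])
        phase = np.random.default_rng(sub + 1).uniform(0, 2 * np.pi)
        t = np.arange(n) / fs
        carriers += amp * env * np.cos(2 * np.pi * f * t + phase)

    exp_, sd = spec.noise_floor
    def bg(tag: int) -> np.ndarray:
        return one_over_f_noise(n, fs, exp_, sd,
                                np.random.default_rng(_carrier_seed(spec.seed, 100 + tag)))

    frontal = 0.5 * carriers + bg(0)
    a1 = carriers + bg(1)
    v1 = carriers + bg(2)

    # schedule: per-epoch states and per-state sample blocks
    states: list[str] = []
    blocks: dict[str, list[tuple[int, int]]] = {s: [] for s in STATES}
    pos = 0.0
    for state, dur in spec.state_schedule:
        n_ep = int(round(dur / EPOCH_S))
        states.extend([state] * n_ep)
        i0, i1 = int(round(pos * fs)), int(round((pos + dur) * fs))
        blocks[state].append((i0, min(i1, n)))
        pos += dur

    # slow-wave sleep signature on the frontal channel
    if blocks["sws"]:
        mask = _ramped_mask(blocks["sws"], n, fs)
        t = np.arange(n) / fs
        sws_env = 1.0 + 0.3 * np.sin(2 * np.pi * 0.1 * t + master.uniform(0, 2 * np.pi))
        frontal += mask * spec.sws_delta_amp * sws_env * np.sin(
            2 * np.pi * spec.sws_delta_freq * t + master.uniform(0, 2 * np.pi))

    # EMG: broadband noise, elevated during active blocks
    emg_noise = np.random.default_rng(_carrier_seed(spec.seed, 200)).standard_normal(n)
    gain = np.ones(n)
    if blocks["active"]:
        gain += (spec.emg_active_gain - 1.0) * _ramped_mask(blocks["active"], n, fs)
    emg = spec.emg_sigma * gain * emg_noise

    # PIR motion events during active blocks
    motion: list[float] = []
    rate_s = spec.motion_rate_active / 60.0
    for i0, i1 in blocks["active"]:
        t0, t1 = i0 / fs, i1 / fs
        k = master.poisson(rate_s * (t1 - t0))
        motion.extend(master.uniform(t0, t1, size=k))
    motion_events = np.sort(np.asarray(motion))

    signals = np.vstack([frontal, a1, v1, emg])

    # artifacts: 200-ms half-sine at 10x channel SD on every EEG channel
    art_starts = list(spec.explicit_artifacts)
    n_art = master.poisson(spec.artifact_rate * spec.duration_s / 60.0)
    art_starts += list(master.uniform(0, spec.duration_s - 0.2, size=n_art))
    w = int(round(0.2 * fs))
    pulse = np.sin(np.pi * np.arange(w) / w)
    artifact_epochs = sorted({int(s // EPOCH_S) for s in art_starts})
    for s in art_starts:
        i0 = int(round(s * fs))
        i1 = min(i0 + w, n)
        for ch in range(3):
            signals[ch, i0:i1] += 10.0 * signals[ch].std() * pulse[: i1 - i0]

    # transmitter gaps: NaN runs on all channels
    gaps = [(float(s), float(l)) for s, l in spec.explicit_gaps]
    n_gap = master.poisson(spec.gap_rate * spec.duration_s / 60.0)
    lo, hi = np.log(spec.gap_length_ms[0]), np.log(spec.gap_length_ms[1])
    for _ in range(n_gap):
        length = float(np.exp(master.uniform(lo, hi)) / 1000.0)
        start = float(master.uniform(0, spec.duration_s - length))
        gaps.append((start, length))
    gaps.sort()
    merged: list[tuple[float, float]] = []
    for g in gaps:  # drop overlaps, keep the earlier gap
        if merged and g[0] < merged[-1][0] + merged[-1][1]:
            continue
        merged.append(g)
    for start, length in merged:
        i0 = int(round(start * fs))
        i1 = max(i0 + 1, int(round((start + length) * fs)))
        signals[:, i0:min(i1, n)] = np.nan

    sync = np.arange(60.0, spec.duration_s, 60.0)
    rec = Recording(
        signals=signals,
        fs=fs,
        channels=[
            ChannelMeta("EEG Frontal", "frontal"),
            ChannelMeta("EEG A1", "temporal_A1"),
            ChannelMeta("EEG V1", "temporal_V1"),
            ChannelMeta("EMG", "emg"),
        ],
        motion_events=motion_events,
        sync_pulses=sync,
        gaps=merged,
        meta={"seed": spec.seed, "preset": preset.name if preset else ""},
    )
    truth = GroundTruth(
        epoch_states=states,
        artifact_epochs=artifact_epochs,
        gaps=merged,
        carrier_freqs=list(spec.carrier_freqs),
        hurst=list(spec.hurst),
        kappa=list(spec.coupling_kappa),
        seed=spec.seed,
        preset=preset.name if preset else "",
    )
    return rec, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def subject_seed(base_seed: int, subject_index: int) -> int:
    return int(np.random.SeedSequence(entropy=base_seed, spawn_key=(subject_index,))
               .generate_state(1)[0] % (2 ** 31))


def generate_cohort(
    groups: dict[str, int],
    base_spec: SyntheticSpec,
    seed: int,
):
    """Yield ``(subject_id, preset_name, Recording, GroundTruth)`` for a cohort.

    ``groups`` maps preset names (keys of :data:`PRESETS`) to subject counts.
    Per-subject seeds are derived deterministically from ``seed``.
    """
    idx = 0
    for preset_name, count in groups.items():
        preset = PRESETS[preset_name]
        for j in range(count):
            sid = f"{preset_name}_{j + 1:02d}"
            spec = replace(base_spec, seed=subject_seed(seed, idx))
            rec, truth = generate_recording(spec, preset)
            yield sid, preset_name, rec, truth
            idx += 1


def write_cohort(
    out_dir: str | Path,
    groups: dict[str, int],
    base_spec: SyntheticSpec,
    seed: int,
    dialect: str = "edf",
) -> list[Path]:
    """Write one EDF (or CSV) per subject plus a ground-truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".edf" if dialect == "edf" else ".csv"
    paths = []
    for sid, preset_name, rec, truth in generate_cohort(groups, base_spec, seed):
        p = out_dir / f"{sid}{ext}"
        write_recording(p, rec, dialect=dialect)
        (out_dir / f"{sid}.truth.json").write_text(truth.to_json())
        paths.append(p)
    return paths
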