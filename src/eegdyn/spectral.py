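"""Per-epoch periodograms and 1-Hz-binned power spectra.

Power is extracted per 5-s epoch as the squared absolute value of the
length-normalized FFT, |FFT(x)/N|², with no taper (a Hann taper is available
behind a flag but off by default), then averaged into integer-center 1-Hz
bins from 1 to 99 Hz and across epochs.  The two temporal-cortex channels
(above auditory and visual cortex) are averaged into a single temporal
signal; the frontal group is the frontal channel alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PowerSpectrum",
    "epoch_power",
    "bin_power",
    "average_channels",
    "power_spectrum",
    "BIN_CENTERS",
]

BIN_CENTERS = np.arange(1, 100)  #: integer bin centers, 1..99 Hz
EPOCH_S = 5.0


@dataclass
class PowerSpectrum:
    """Per-channel-group power in 1-Hz bins, 1–99 Hz, averaged over epochs."""

    freqs: np.ndarray      #: integer bin centers (99 bins)
    power: np.ndarray      #: µV² per bin
    n_epochs: int
    channel_group: str

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.size != 99 or self.power.size != 99:
            raise ValueError("expected 99 one-Hz bins (1..99 Hz)")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")
        if self.n_epochs < 1:
            raise ValueError("need at least one epoch")

    def to_frame(self, subject: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "freq_bin": self.freqs.astype(int),
            "power": self.power,
            "n_epochs": self.n_epochs,
            "channel_group": self.channel_group,
        })
        if subject is not None:
            df.insert(0, "subject", subject)
        return df


def epoch_power(epoch_signal: np.ndarray, fs: float, taper: bool = False
                ) -> tuple[np.ndarray, np.ndarray]:
    """Raw periodogram of one gap-free 5-s epoch: |FFT(x)/N|².

    Returns ``(freqs, power)`` at the FFT-native resolution (0.2 Hz for 5-s
    epochs), one-sided (non-negative frequencies, no doubling), so that the
    sum over the full two-sided spectrum satisfies Parseval,
    Σ|FFT(x)/N|² = mean(x²).
    """
    x = np.asarray(epoch_signal, dtype=float)
    n_expected = int(round(EPOCH_S * fs))
    if x.ndim != 1 or x.size != n_expected:
        raise ValueError(f"epoch must be {n_expected} samples (5 s at {fs} Hz), got {x.shape}")
    if np.isnan(x).any():
        raise ValueError("epoch contains NaN (gap); interpolate or exclude first")
    if taper:
        w = np.hanning(x.size)
        x = (x - x.mean()) * w * np.sqrt(x.size / (w ** 2).sum())
    n = x.size
    spec = np.abs(np.fft.rfft(x) / n) ** 2
    freqs = np.fft.rfftfreq(n, 1 / fs)
    return freqs, spec


def bin_power(freqs: np.ndarray, periodogram: np.ndarray) -> np.ndarray:
    """Average a native-resolution periodogram into 1-Hz bins, 1–99 Hz.

    Bin f covers native frequencies in [f − 0.5, f + 0.5): a half-open,
    center-integer partition (a tone at 10.4 Hz lands in bin 10, one at
    10.5 Hz in bin 11).
    """
    freqs = np.asarray(freqs)
    periodogram = np.asarray(periodogram)
    out = np.empty(BIN_CENTERS.size)
    idx = np.floor(freqs + 0.5).astype(int)  # bin index of each native freq
    for j, f in enumerate(BIN_CENTERS):
        sel = idx == f
        out[j] = periodogram[sel].mean() if sel.any() else 0.0
    return out


def power_spectrum(epochs: np.ndarray, fs: float, channel_group: str,
                   taper: bool = False) -> PowerSpectrum:
    """Binned power averaged over epochs (rows of ``epochs``)."""
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    binned = []
    for row in epochs:
        freqs, p = epoch_power(row, fs, taper=taper)
        binned.append(bin_power(freqs, p))
    return PowerSpectrum(
        freqs=BIN_CENTERS.copy(),
        power=np.mean(binned, axis=0),
        n_epochs=epochs.shape[0],
        channel_group=channel_group,
    )


def average_channels(spectra: list[PowerSpectrum], channel_group: str) -> PowerSpectrum:
    """Arithmetic mean of per-channel spectra into one channel-group spectrum
    (temporal group = mean of the available A1/V1 channels)."""
    if not spectra:
        raise ValueError(f"no channels available for group {channel_group!r}")
    n_ep = spectra[0].n_epochs
    for s in spectra:
        if s.n_epochs != n_ep:
            raise ValueError("channel spectra must share the epoch count")
    return PowerSpectrum(
        freqs=spectra[0].freqs.copy(),
        power=np.mean([s.power for s in spectra], axis=0),
        n_epochs=n_ep,
        channel_group=channel_group,
    )
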