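"""Independent reference implementations used only as test oracles.

Deliberately naive: explicit window loops, per-window polynomial fits, no
shared code with the vectorized implementations in the package (the GESD
outlier test is shared, but is itself verified against a published worked
example elsewhere in the suite).
"""

from __future__ import annotations

import numpy as np

from eegdyn.stats import generalized_esd


def naive_detrended_sd(window: np.ndarray) -> float:
    t = np.arange(window.size, dtype=float)
    coef = np.polyfit(t, window, 1)
    resid = window - np.polyval(coef, t)
    return float(np.sqrt(np.mean(resid ** 2)))


def naive_dfa(envelope, fs, win_min_s, win_max_s=20.0, overlap=0.8, n_sizes=10):
    """Loop-based DFA exponent over pooled segments."""
    segs = [np.asarray(envelope)] if np.ndim(envelope[0]) == 0 else \
        [np.asarray(s) for s in envelope]
    longest = max(s.size for s in segs)
    nmin = int(round(win_min_s * fs))
    nmax = min(int(round(win_max_s * fs)), longest)
    sizes = np.unique(np.round(np.geomspace(nmin, nmax, n_sizes)).astype(int))
    log_s, log_f = [], []
    for size in sizes:
        step = max(1, int(round((1 - overlap) * size)))
        fl = []
        for seg in segs:
            prof = np.cumsum(seg - np.mean(seg))
            for st in range(0, seg.size - size + 1, step):
                fl.append(naive_detrended_sd(prof[st:st + size]))
        if fl:
            log_s.append(np.log10(size / fs))
            log_f.append(np.log10(np.mean(fl)))
    return float(np.polyfit(log_s, log_f, 1)[0])


def naive_fei(envelope, fs, win_s=5.0, overlap=0.8, alpha=0.05):
    """Loop-based fEI: per-window mean amplitude and the SD of the
    amplitude-normalized, detrended within-window profile."""
    segs = [np.asarray(envelope)] if np.ndim(envelope[0]) == 0 else \
        [np.asarray(s) for s in envelope]
    size = int(round(win_s * fs))
    step = max(1, int(round((1 - overlap) * size)))
    amps, flucts = [], []
    for seg in segs:
        for st in range(0, seg.size - size + 1, step):
            w = seg[st:st + size]
            w_amp = float(np.mean(w))
            prof = np.cumsum(w - w_amp) / w_amp
            amps.append(w_amp)
            flucts.append(naive_detrended_sd(prof))
    amps = np.asarray(amps)
    flucts = np.asarray(flucts)
    max_out = max(1, int(round(0.1 * amps.size)))
    out = np.union1d(generalized_esd(amps, max_out, alpha),
                     generalized_esd(flucts, max_out, alpha))
    keep = np.setdiff1d(np.arange(amps.size), out)
    r = float(np.corrcoef(amps[keep], flucts[keep])[0, 1])
    return 1.0 - r


def gph_hurst(x: np.ndarray) -> float:
    """Log-periodogram (GPH) Hurst estimate for a stationary series.

    Regresses log I(f_j) on log f_j over the lowest sqrt(n) Fourier
    frequencies; for fGn the spectral slope is 1 − 2H.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    freqs = np.fft.rfftfreq(n)
    per = np.abs(np.fft.rfft(x - x.mean())) ** 2 / n
    m = int(np.sqrt(n))
    sel = slice(1, m + 1)
    slope = np.polyfit(np.log(freqs[sel]), np.log(per[sel]), 1)[0]
    return float((1.0 - slope) / 2.0)
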