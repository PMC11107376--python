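"""1-Hz-binned resting-state power spectra and the planted genotype contrast.

Computes per-epoch periodograms (|FFT/N|^2, no taper), averages them into
1-Hz bins from 1-99 Hz and across the two temporal-cortex channels, for one
wild-type-like and one knockout-like subject.
"""

import dataclasses

import numpy as np

import eegdyn as ed
from eegdyn.pipeline import score_recording
from eegdyn.resting import resting_segments_signal

spec = ed.SyntheticSpec(duration_s=200.0, fs=500.0,
                        state_schedule=(("rest", 200.0),))

for name in ("WT", "KO"):
    rec, _ = ed.generate_recording(
        dataclasses.replace(spec, seed=1), ed.PRESETS[name])
    rec2, labels, segset = score_recording(rec)
    segs = resting_segments_signal(rec2, segset, "temporal")
    ep = int(5 * rec2.fs)
    epochs = np.concatenate([s[: (s.size // ep) * ep].reshape(-1, ep)
                             for s in segs])
    ps = ed.power_spectrum(epochs, rec2.fs, "temporal")
    gamma = ps.power[(ps.freqs >= 30) & (ps.freqs <= 90)].mean()
    theta = ps.power[(ps.freqs >= 4) & (ps.freqs <= 8)].mean()
    peak = int(ps.freqs[np.argmax(ps.power[ps.freqs > 20]) + 20])
    print(f"{name}: {ps.n_epochs} epochs | mean gamma-band power "
          f"{gamma:.3f} uV^2/bin | theta {theta:.3f} | gamma peak near {peak} Hz")
# Interpretation: the knockout preset plants elevated broadband power and a
# stronger 40-Hz oscillation, so its gamma-band bins sit clearly above the
# wild-type values while the spectrum's shape stays the same.
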