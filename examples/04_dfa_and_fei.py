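"""Long-range temporal correlations (DFA) and the functional E/I ratio.

Generates three 300-s gamma oscillations whose envelopes carry the same
long-range temporal correlations (Hurst 0.75) but different planted
amplitude-fluctuation coupling, then measures both biomarkers through the
full pipeline path: narrowband Hamming filter at the 40-Hz bin, Hilbert
envelope, DFA, fEI.
"""

import eegdyn as ed

for kappa, label in [(-0.3, "inhibition-dominated"),
                     (0.0, "balanced"),
                     (+0.3, "excitation-dominated")]:
    spec = ed.SyntheticSpec(duration_s=300.0, fs=1000.0,
                            coupling_kappa=(0.0, 0.0, kappa), seed=3)
    sig = ed.generate_coupled_oscillation(spec, 2)      # 40-Hz carrier
    be = ed.band_envelope(sig, spec.fs, 40.0)
    d = ed.dfa(be.valid, spec.fs, f=40.0)
    r = ed.fei(be.valid, spec.fs, dfa_exponent=d.exponent)
    print(f"kappa={kappa:+.1f} ({label:>22}): DFA exponent {d.exponent:.2f} "
          f"(fit r^2 {d.fit_r2:.3f}), fEI {r.fei:.2f} "
          f"[{r.n_windows_used} windows, {r.n_outliers_removed} outliers removed]")
# Interpretation: fEI reads ~1 for the balanced signal, below 1 when window
# fluctuations grow with window amplitude (inhibition-dominated), above 1
# for the opposite coupling; the DFA exponent stays above the 0.6 validity
# gate in all three cases, so every fEI value is defined.
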