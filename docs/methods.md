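# Methods

This note documents the models, parameters, numerical choices and known
limitations of `eegdyn`. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## 1. The measurement pipeline

### Narrowband envelopes

Each 1-Hz bin *f* is isolated with a Hamming-window FIR bandpass at
[*f* − 0.5, *f* + 0.5] Hz applied zero-phase (forward–backward, i.e. the
squared amplitude response; in practice one frequency-domain multiplication
by the squared real response of the symmetric kernel). The envelope is the
magnitude of the analytic signal of the demeaned filtered trace. Samples
within one kernel length of each segment end are flagged and excluded from
all windowing.

**Filter length.** The kernel targets a 4-Hz transition width
(≈ 0.83 s at 1 kHz; order capped at one-third of the segment). This is a
deliberate compromise, and the single most consequential numerical choice
in the package:

* The kernel's temporal support must stay well below the smallest DFA
  window (1 s for bins above 13 Hz). A much narrower transition (say
  0.25 Hz, a ~13-s kernel) smooths every envelope across the entire DFA
  window range, and the measured exponent of *any* signal — including
  white noise — saturates near 0.9, destroying both the exponent's meaning
  and the fEI validity gate.
* Selectivity must stay useful: with the 4-Hz transition the two-pass
  Hamming response still attenuates a tone 3 Hz outside the bin by far
  more than 20 dB, so a planted carrier contaminates only its immediate
  neighbourhood of bins.

Even so, a 1-Hz passband forces an envelope autocorrelation time of order
1 s, so the smallest DFA windows are never fully in the scaling regime:
an *unstructured* signal (white noise passed through the filter) measures
an envelope DFA exponent of roughly 0.63–0.77 rather than 0.5, and planted
persistent envelopes measure somewhat above their nominal Hurst exponent.
Consequences: (i) the DFA > 0.6 gate reliably distinguishes genuine
envelopes fed to `dfa`/`fei` directly, but cannot be expected to gate out
noise-floor bins of a full `metric_spectrum`; (ii) through-filter DFA
values are best used for *contrasts* (group differences in the same bins),
which the generator plants and the tests verify directionally. Ground-truth
Hurst recovery (mean absolute error ≤ 0.05 for H between 0.55 and 0.85) is
verified on envelopes directly, where no filter intervenes.

### DFA

Per contiguous segment the profile is the cumulative sum of the demeaned
envelope; the profile never runs across segment boundaries (concatenating
across discontinuities fabricates long-range structure). Ten log-spaced
window sizes span the band-specific minimum (4 s below 8 Hz, 2 s at
8–13 Hz, 1 s above) to 20 s, de-duplicated after rounding to whole
samples; the step is (1 − 0.8) × size. Windows are linearly detrended
(first order); the fluctuation is the population SD. The exponent is the
least-squares slope of log₁₀ mean fluctuation on log₁₀ size, pooled over
segments; fewer than two usable sizes yields NaN. When no segment reaches
20 s the largest size shrinks to the longest segment and the result is
marked truncated.

### fEI

Windows of 5 s with 0.8 overlap (1-s steps), fully inside one segment.
w_amp is the window-mean envelope; the within-window profile (equivalently
the global profile restricted to the window — linear detrending removes
the difference exactly) is divided by w_amp, linearly detrended, and its
SD is w_fluct. A two-sided generalized ESD test (α = 0.05, at most
max(1, 10% of windows) outliers, applied independently to the amplitude
and fluctuation series, union removed) precedes the Pearson correlation;
fEI = 1 − r. Fewer than 10 surviving windows, a degenerate series, or a
DFA exponent ≤ 0.6 yields a missing value with a reason code. The
procedure reads "mean amplitude" as the mean of the *envelope* per window
and applies normalization and detrending to the *profile*; this is the
only reading under which the normalization (division by w_amp) makes the
statistic scale-invariant, which the tests verify to 10⁻⁶.

### Spectral power

Per 5-s epoch: |FFT(x)/N|² at the native 0.2-Hz resolution, no taper (a
Hann taper exists behind a flag, default off). One-sided values are
reported without doubling; Parseval is verified on the two-sided sum. Bin
*f* averages native frequencies in [*f* − 0.5, *f* + 0.5) — half-open,
center-integer. Epochs are averaged after binning; the temporal group is
the arithmetic mean of the A1 and V1 channels.

## 2. Vigilance scoring and signal quality

Five-second epochs, scored from the 70-Hz low-passed frontal channel:

* **sws** — mean delta-band (0.5–4 Hz) envelope > k_delta × baseline;
* **active** — any motion event in the epoch, or EMG RMS > k_emg × baseline;
* **rest** — neither; a rest epoch directly after sws is relabeled
  **post_sleep** (guards against scoring REM sleep as rest);
* **signal_loss** — any gap > 10 ms ("more than 10 ms" is read strictly:
  exactly 10 ms is kept); shorter gaps are bridged by a straight line
  between the flanking samples; a gap touching the recording boundary has
  no flanking sample and excludes its epoch;
* **artifact** — a rest epoch whose peak amplitude exceeds k_amp robust
  SDs (1.4826 × MAD, recording-wide), whose 70–99 Hz power fraction
  exceeds k_hf, or which contains more than k_spk sub-5-ms excursions
  above spike_sd robust SDs.

Defaults: k_delta = 3, k_emg = 2.5, k_amp = 6, k_hf = 0.5, k_spk = 3,
spike_sd = 5 — declared, tunable configuration values validated against
synthetic ground truth (≥ 95% label agreement, and rest recall/precision
≥ 0.95, on scheduled recordings), not quantities estimated from data. The
baseline for the delta and EMG thresholds is the *lower quartile* of the
per-epoch statistic rather than the median: identical in rest-dominated
recordings, but still meaningful when sleep or movement occupies more than
half the epochs (the median would then sit on the elevated state and the
threshold could never trigger).

A recording enters analysis only with ≥ 80 s of resting-state signal and
≤ 50% of its resting data lost to the gap/artifact rules; exclusions carry
machine-readable reasons (`below_min_rest`, `rejection_over_half`).

## 3. The synthetic generator

The generator produces what the analysis measures, with the true values
known by construction. It is a *measurement-level* surrogate: nothing in
it models synaptic physiology, and κ is defined directly as the quantity
fEI estimates, not as a biophysical E/I ratio.

**Envelopes.** Fractional Gaussian noise with exact target autocovariance
(circulant embedding / Davies–Harte, with a spectral-synthesis fallback if
an embedding were non-positive-definite), standardized and passed through
a lognormal map exp(σ·g) with σ = 0.3, normalized to unit mean. The
lognormal (multiplicative) form is essential, not cosmetic: on a
multiplicative envelope the local fluctuation scales with the local level,
so the amplitude-normalized window fluctuation is independent of window
amplitude and the uncoupled state calibrates to fEI ≈ 1. An
additive-offset envelope (fGn plus a constant) is homoskedastic; dividing
a level-independent fluctuation by w_amp then manufactures a negative
correlation and biases fEI upward by ≈ +0.10 at these parameters. The
lognormal map preserves the Hurst exponent (measured bias < 0.02 at
σ = 0.3).

**Coupling.** In consecutive non-overlapping 5-s blocks, demeaned envelope
deviations are scaled by exp(−κ·z), z being the z-scored log block-mean
amplitude; block means are untouched up to a positivity clip at 10⁻⁹
(exact in the median block; within 2% in blocks where clipping bites at
|κ| ≈ 0.4). z-scoring makes κ a duration-independent effect size; the
raw block-mean ratio of an LRTC envelope varies by only a few percent over
5-s blocks and would plant an undetectably weak correlation. κ = 0 leaves
the envelope untouched; fEI is strictly increasing in κ at matched seeds.

**Recordings.** Frontal + two temporal EEG channels share the planted
oscillations (a common source seen by every electrode) over independent
1/f backgrounds (exponent 1, 10 µV SD); default carriers 2.5, 6 and 40 Hz
at 4, 8 and 20 µV with Hurst 0.60/0.70/0.75. The 40-µV²-scale gamma
carrier keeps in-band SNR high; at low SNR the additive noise floor in the
recovered envelope reintroduces the additive-envelope bias described
above (measured: balanced fEI drifts from ≈ 1.00 at 20 µV to ≈ 1.07 at
6 µV). During `sws` blocks the frontal channel carries 2.5-Hz waves at
50 µV with raised-cosine onsets; during `active` blocks EMG RMS rises
5-fold and PIR motion events fire at 20/min. Transmitter gaps (all
channels, NaN runs, log-uniform 2–50 ms) and 200-ms half-sine transients
at 10× the channel SD are injected at configurable rates; one sync pulse
per minute. Identical spec + seed ⇒ bit-identical output; per-subject
seeds derive from a master seed via `SeedSequence`.

**Presets.** `KO` vs `WT` plants the reported directions of the Fragile-X
model's group differences: broadband power × 1.4 with gamma-carrier power
× 1.6, gamma Hurst + 0.08, gamma κ = −0.3 (inhibition-shifted).
Pharmacological presets (`saline`, `clz_low`, `clz_high`, `mpep`) plant a
GABA-potentiator-like profile — reduced delta power, raised gamma LRTC,
negative gamma κ — against a neutral baseline. Magnitudes are design
choices sized to be recoverable by a 12-vs-12 cohort; only their
directions mirror reported effects.

**What the generator does not emulate.** Real vigilance transitions are
gradual and REM is absent by design (the post_sleep rule is the only REM
guard, as in the scoring convention it implements). Real envelopes are not
exactly lognormal, electrode gain differences, drift and line noise are
absent, and oscillations do not change with vigilance state. Passing tests
therefore demonstrate that the *estimators and rules* behave as specified
on signals with known structure — not that any particular biological
effect size would be recovered from real data.

## 4. Group comparison

Subject-level spectra are compared as difference waves: per-bin group-mean
difference with a confidence band; frequency ranges where the band
excludes zero are called significant. For one contrast the level is 95%;
for k simultaneous contrasts it is Bonferroni-widened to 1 − 0.05/k
(98.3% for a triple comparison).

The band is a subject-level bootstrap (default 2000 resamples, seed
mandatory): resampling whole subjects preserves the correlation of
neighbouring bins within a spectrum, the feature that parametric
spectrum-curve models must otherwise correct for explicitly. This
deliberately replaces a generalized additive mixed model: the package does
not reproduce GAMM fits, explained-variance or AIC comparisons, and the
bootstrap cannot mirror per-animal smooth random effects — an
acknowledged approximation.

Two band families are provided. `pointwise` (default) is the percentile
band per bin; over 99 bins it scatters isolated false-positive bins at the
nominal per-bin rate, which is expected and visible in the examples.
`simultaneous` controls the family-wise error over the whole spectrum via
a *studentized permutation* sup-test (group labels permuted, per-
permutation re-studentization, sup over bins). A bootstrap sup-band was
measured to undercover badly at small group sizes (per-bin statistics
have t-tails with few degrees of freedom that bootstrap resampling cannot
reproduce); the permutation version holds its level at any n and is what
the null-coverage test exercises.

Bins with fewer than 3 finite subject values in either group (e.g. gated
fEI) are indeterminate: NaN, never significant. An optional display
smoother — discrete second-difference ridge with GCV-chosen penalty,
applied per draw — mirrors smooth fitted spectra; it is off by default
and off in all coverage checks.

## 5. Numerical choices

* Detrended-fluctuation windows are evaluated via cumulative sums (O(N)
  per window size) in extended precision (`longdouble`): the running sums
  grow with the profile while the residual is orders of magnitude smaller,
  and float64 accumulation loses ~10 significant digits on minute-long
  segments. Vectorized DFA and fEI agree with naive loop implementations
  to 10⁻¹⁰ on 60–100-s fixtures.
* Gaps are annotations on an intact sample grid (NaN runs in memory),
  never deleted samples, so epoch timing and the 10-ms rule are exact; the
  EDF writer stores gap samples as a flat-line sentinel and the events/
  gaps/roles in a JSON sidecar (plain EDF has no annotation stream), and
  the reader falls back to NaN-run/flat-run detection without a sidecar.
* Downsampling (default target 1000 Hz) is polyphase with linear NaN
  bridging before the anti-alias filter and re-imposition of gap NaNs on
  the new grid; event and gap times are in seconds and unchanged.
* Motion-clock alignment is a piecewise-linear map through the
  once-per-minute sync-pulse pairs with linear extrapolation beyond the
  span; the maximum absolute correction is reported as residual drift.
* The generalized ESD critical values use the t-distribution form with a
  single vectorized quantile call; the implementation reproduces the
  classic 54-point worked example (three outliers) exactly.
* EDF output is 16-bit; round-trips are exact to one quantization step of
  the per-channel physical range.

## 6. Problem sizes used by the tests

Hurst recovery and calibration use 2¹⁷-sample envelopes and 300-s signals
at 1000 Hz over 20 seeds; the end-to-end cohort check uses 12 + 12
subjects × 240 s at 500 Hz, analyzed at all 99 bins on the temporal
group; scoring validation uses 600-s scheduled recordings. These sizes
were chosen so the planted effects dominate estimator noise by a
comfortable margin while the whole suite stays conveniently runnable on a
laptop-class single core.
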