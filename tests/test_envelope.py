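"""Narrowband envelopes, DFA, fEI: identities, invariances, oracle
equivalence, and the generalized ESD outlier test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eegdyn as ed
from eegdyn.envelope import BandScheme
from eegdyn.stats import generalized_esd

from oracles import naive_dfa, naive_fei


FS = 250.0


class TestBandEnvelope:
    def test_pure_tone_envelope_equals_amplitude(self):
        t = np.arange(int(60 * FS)) / FS
        be = ed.band_envelope(3.7 * np.sin(2 * np.pi * 40.0 * t), FS, 40.0)
        assert np.all(np.abs(be.valid / 3.7 - 1) < 0.02)

    def test_off_band_tone_attenuated(self):
        """A tone 3 Hz off the bin center is attenuated by >= 20 dB."""
        t = np.arange(int(60 * FS)) / FS
        e_in = np.median(ed.band_envelope(np.sin(2 * np.pi * 40.0 * t), FS, 40.0).valid)
        e_off = np.median(ed.band_envelope(np.sin(2 * np.pi * 43.0 * t), FS, 40.0).valid)
        assert 20 * np.log10(e_in / max(e_off, 1e-300)) >= 20.0

    def test_am_tone_tracks_modulation(self):
        """Envelope of A(t) sin(2 pi f t) follows slow A(t) within 5% RMS."""
        t = np.arange(int(120 * FS)) / FS
        a = 1.0 + 0.4 * np.sin(2 * np.pi * 0.05 * t)
        be = ed.band_envelope(a * np.sin(2 * np.pi * 30.0 * t), FS, 30.0)
        sl = slice(be.n_edge, -be.n_edge)
        rms = np.sqrt(np.mean((be.valid - a[sl]) ** 2)) / a.mean()
        assert rms < 0.05

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="short"):
            ed.band_envelope(np.zeros(100), FS, 40.0)

    def test_nan_segment_rejected(self):
        x = np.zeros(int(30 * FS))
        x[5] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            ed.band_envelope(x, FS, 40.0)


class TestBandScheme:
    def test_band_specific_minimum_windows(self):
        s = BandScheme()
        assert s.dfa_win_min_s(4.0) == 4.0
        assert s.dfa_win_min_s(7.9) == 4.0
        assert s.dfa_win_min_s(8.0) == 2.0
        assert s.dfa_win_min_s(13.0) == 2.0
        assert s.dfa_win_min_s(14.0) == 1.0

    def test_bad_overlap(self):
        with pytest.raises(ValueError):
            BandScheme(overlap=1.0)


class TestDFA:
    def test_white_noise_exponent_half(self, rng):
        env = np.abs(rng.standard_normal(2 ** 16)) + 0.1
        d = ed.dfa(env, 1000.0, f=40.0)
        assert d.exponent == pytest.approx(0.5, abs=0.05)

    def test_affine_invariance(self, balanced_envelope):
        """DFA exponent unchanged under y -> a*y + b (a > 0)."""
        d0 = ed.dfa(balanced_envelope, FS, f=40.0)
        d1 = ed.dfa(3.2 * balanced_envelope + 7.0, FS, f=40.0)
        assert d1.exponent == pytest.approx(d0.exponent, abs=1e-6)

    def test_oracle_equivalence(self, balanced_envelope):
        """Vectorized DFA equals the explicit-loop oracle to 1e-10."""
        env = balanced_envelope[: int(60 * FS)]
        d = ed.dfa(env, FS, f=40.0)
        ref = naive_dfa(env, FS, win_min_s=1.0)
        assert d.exponent == pytest.approx(ref, abs=1e-10)

    def test_oracle_equivalence_pooled_segments(self, balanced_envelope):
        segs = [balanced_envelope[:15000], balanced_envelope[20000:42000]]
        d = ed.dfa(segs, FS, f=40.0)
        ref = naive_dfa(segs, FS, win_min_s=1.0)
        assert d.exponent == pytest.approx(ref, abs=1e-10)

    def test_result_diagnostics(self, balanced_envelope):
        d = ed.dfa(balanced_envelope, FS, f=40.0)
        assert np.all(np.diff(d.window_sizes_s) > 0)
        assert np.all(d.mean_fluctuations > 0)
        assert 0.9 < d.fit_r2 <= 1.0
        assert d.window_sizes_s[-1] == pytest.approx(20.0, rel=0.01)

    def test_too_short_gives_nan(self):
        d = ed.dfa(np.ones(100), FS, f=40.0)
        assert np.isnan(d.exponent)

    def test_truncation_recorded(self, balanced_envelope):
        d = ed.dfa(balanced_envelope[: int(10 * FS)], FS, f=40.0)
        assert d.truncated
        assert d.window_sizes_s[-1] <= 10.0


class TestFEI:
    def test_gate_blocks_low_dfa(self, balanced_envelope):
        """No fEI when the DFA exponent is at or below 0.6."""
        for expo in (0.35, 0.55, 0.6):
            r = ed.fei(balanced_envelope, FS, dfa_exponent=expo)
            assert not r.valid
            assert np.isnan(r.fei)
            assert r.reason == "dfa_gate"

    def test_white_noise_envelope_gated_end_to_end(self, rng):
        """A white-noise amplitude envelope has DFA ~ 0.5, so fEI is missing
        when the exponent is measured from the data itself."""
        env = np.abs(rng.standard_normal(2 ** 16)) + 0.1
        r = ed.fei(env, 1000.0)
        assert not r.valid and np.isnan(r.fei)

    def test_fei_plus_r_is_one(self, balanced_envelope):
        r = ed.fei(balanced_envelope, FS, dfa_exponent=0.75)
        assert r.valid
        assert r.fei + r.r == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= r.fei <= 2.0

    def test_scale_invariance(self, balanced_envelope):
        """fEI unchanged under global amplitude scaling (y -> a*y)."""
        r0 = ed.fei(balanced_envelope, FS, dfa_exponent=0.75)
        r1 = ed.fei(123.4 * balanced_envelope, FS, dfa_exponent=0.75)
        assert r1.fei == pytest.approx(r0.fei, abs=1e-6)

    def test_oracle_equivalence(self, balanced_envelope):
        """Vectorized fEI equals the explicit window-loop oracle to 1e-10."""
        env = balanced_envelope[: int(100 * FS)]
        r = ed.fei(env, FS, dfa_exponent=0.75)
        assert r.fei == pytest.approx(naive_fei(env, FS), abs=1e-10)

    def test_insufficient_windows(self, balanced_envelope):
        r = ed.fei(balanced_envelope[: int(6 * FS)], FS, dfa_exponent=0.8)
        assert not r.valid
        assert r.reason == "insufficient windows"


class TestMetricSpectrum:
    def test_planted_carrier_bin_valid(self):
        """With one planted 40-Hz carrier the carrier bin passes the gate and
        carries a balanced fEI."""
        spec = ed.SyntheticSpec(duration_s=180.0, fs=500.0,
                                state_schedule=(("rest", 180.0),), seed=2)
        sig = ed.generate_coupled_oscillation(spec, 2)
        scheme = BandScheme(bin_centers=(38, 40, 42))
        ms = ed.metric_spectrum([sig], 500.0, "temporal", scheme)
        i40 = list(ms.freqs).index(40.0)
        assert ms.fei_results[i40].valid
        assert ms.dfa_results[i40].exponent > 0.6
        assert 0.6 < ms.fei_results[i40].fei < 1.4

    def test_failing_bin_does_not_abort(self):
        rng = np.random.default_rng(0)
        sig = rng.standard_normal(int(30 * FS))
        scheme = BandScheme(bin_centers=(10, 40, 99))
        ms = ed.metric_spectrum([sig], FS, "temporal", scheme)
        assert len(ms.dfa_results) == 3
        df = ms.to_frame("s1")
        assert list(df["freq_bin"]) == [10, 40, 99]

    def test_validity_flags_consistent_with_gate(self):
        rng = np.random.default_rng(1)
        sig = rng.standard_normal(int(60 * FS))
        scheme = BandScheme(bin_centers=(20, 40, 60))
        ms = ed.metric_spectrum([sig], FS, "temporal", scheme)
        for d, e in zip(ms.dfa_results, ms.fei_results):
            if not np.isfinite(d.exponent) or d.exponent <= scheme.dfa_gate:
                assert not e.valid


class TestGeneralizedESD:
    def test_published_worked_example(self):
        """Rosner's 54-point example: exactly the three largest values are
        declared outliers (k up to 10, alpha 0.05)."""
        y = np.array([
            -0.25, 0.68, 0.94, 1.15, 1.20, 1.26, 1.26, 1.34, 1.38, 1.43,
            1.49, 1.49, 1.55, 1.56, 1.58, 1.65, 1.69, 1.70, 1.76, 1.77,
            1.81, 1.91, 1.94, 1.96, 1.99, 2.06, 2.09, 2.10, 2.14, 2.15,
            2.23, 2.24, 2.26, 2.35, 2.37, 2.40, 2.47, 2.54, 2.62, 2.64,
            2.90, 2.92, 2.92, 2.93, 3.21, 3.26, 3.30, 3.59, 3.68, 4.30,
            4.64, 5.34, 5.42, 6.01])
        out = generalized_esd(y, max_outliers=10, alpha=0.05)
        assert sorted(out) == [51, 52, 53]

    def test_clean_gaussian_mostly_clean(self, rng):
        x = rng.standard_normal(200)
        out = generalized_esd(x, max_outliers=20, alpha=0.05)
        assert out.size <= 3

    @given(st.floats(20, 1000))
    @settings(max_examples=20, deadline=None)
    def test_gross_outlier_always_flagged(self, magnitude):
        x = np.concatenate([np.random.default_rng(7).standard_normal(100),
                            [magnitude]])
        out = generalized_esd(x, max_outliers=10, alpha=0.05)
        assert 100 in out

    def test_constant_series(self):
        assert generalized_esd(np.ones(50), 5).size == 0
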