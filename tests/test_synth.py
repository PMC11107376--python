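"""Generator contracts: determinism, planted Hurst exponents, coupling
direction, schedules, gaps and presets."""

import numpy as np
import pytest

import eegdyn as ed
from eegdyn.synth import apply_coupling, band_of, subject_seed

from oracles import gph_hurst


class TestEnvelope:
    def test_deterministic_and_positive(self):
        a = ed.generate_envelope(0.7, 2048, 250.0, seed=5)
        b = ed.generate_envelope(0.7, 2048, 250.0, seed=5)
        assert np.array_equal(a, b)
        assert np.all(a > 0)
        assert a.mean() == pytest.approx(1.0)

    def test_seed_changes_output(self):
        a = ed.generate_envelope(0.7, 2048, 250.0, seed=5)
        b = ed.generate_envelope(0.7, 2048, 250.0, seed=6)
        assert not np.array_equal(a, b)

    @pytest.mark.parametrize("bad_h", [0.0, 1.0, -0.3, 1.7])
    def test_hurst_out_of_range(self, bad_h):
        with pytest.raises(ValueError):
            ed.generate_envelope(bad_h, 2048, 250.0, seed=1)

    def test_too_short(self):
        with pytest.raises(ValueError):
            ed.generate_envelope(0.7, 512, 250.0, seed=1)

    def test_uncorrelated_limit_dfa_half(self):
        """H=0.5 envelope measures a DFA exponent near 0.5."""
        env = ed.generate_envelope(0.5, 2 ** 17, 1000.0, seed=1)
        d = ed.dfa(env, 1000.0, f=40.0)
        assert d.exponent == pytest.approx(0.5, abs=0.05)

    def test_persistent_envelope_agrees_with_spectral_estimator(self):
        """DFA of H=0.8 envelopes matches H and an independent
        log-periodogram Hurst estimate of the same series (seed-averaged:
        the spectral estimator has a per-seed SD near 0.045)."""
        dfa_vals, gph_vals = [], []
        for seed in range(1, 7):
            env = ed.generate_envelope(0.8, 2 ** 17, 1000.0, seed=seed)
            dfa_vals.append(ed.dfa(env, 1000.0, f=40.0).exponent)
            # log of the lognormal envelope is exactly the underlying fGn
            gph_vals.append(gph_hurst(np.log(env)))
        assert np.mean(dfa_vals) == pytest.approx(0.8, abs=0.05)
        assert np.mean(gph_vals) == pytest.approx(0.8, abs=0.05)
        assert np.mean(dfa_vals) == pytest.approx(np.mean(gph_vals), abs=0.05)

    def test_fgn_exact_autocovariance(self):
        """Sample autocovariance of synthesized fGn matches the closed form."""
        rng = np.random.default_rng(3)
        acc = np.zeros(4)
        n_rep = 200
        for _ in range(n_rep):
            x = ed.fractional_gaussian_noise(0.75, 512, rng)
            for k in range(4):
                acc[k] += np.mean(x[: 512 - k] * x[k:])
        acc /= n_rep
        k = np.arange(4, dtype=float)
        expected = 0.5 * ((k + 1) ** 1.5 - 2 * k ** 1.5 + np.abs(k - 1) ** 1.5)
        assert np.allclose(acc, expected, atol=0.05)


class TestCoupling:
    def test_zero_kappa_identity(self):
        env = ed.generate_envelope(0.7, 50000, 250.0, seed=1)
        assert np.array_equal(apply_coupling(env, 250.0, 0.0), env)

    def test_block_means_preserved(self):
        env = ed.generate_envelope(0.7, 50000, 250.0, seed=1)
        out = apply_coupling(env, 250.0, -0.4)
        b = int(5 * 250)
        nb = env.size // b
        m0 = env[: nb * b].reshape(nb, b).mean(1)
        m1 = out[: nb * b].reshape(nb, b).mean(1)
        # exact where no positivity clipping occurred; within 2% elsewhere
        assert np.allclose(m0, m1, rtol=0.02)
        assert np.median(np.abs(m0 - m1)) < 1e-12

    def test_degenerate_kappa_rejected(self):
        env = ed.generate_envelope(0.7, 50000, 250.0, seed=1)
        with pytest.raises(ValueError):
            apply_coupling(env, 250.0, 4.0)

    def test_sign_direction_on_envelope(self):
        """Planted negative coupling reads as fEI < 1, positive as > 1, and
        fEI(+0.5) > fEI(-0.5) at identical seeds."""
        fs = 250.0
        lo, hi = [], []
        for seed in range(3):
            env = ed.generate_envelope(0.75, 75000, fs, seed=seed)
            f_neg = ed.fei(apply_coupling(env, fs, -0.5), fs, dfa_exponent=0.75).fei
            f_pos = ed.fei(apply_coupling(env, fs, +0.5), fs, dfa_exponent=0.75).fei
            lo.append(f_neg)
            hi.append(f_pos)
            assert f_pos > f_neg
        assert np.mean(lo) < 1.0 < np.mean(hi)


class TestSpecValidation:
    def test_schedule_must_sum(self):
        with pytest.raises(ValueError, match="schedule"):
            ed.SyntheticSpec(duration_s=100.0, state_schedule=(("rest", 50.0),))

    def test_fs_vs_carriers(self):
        with pytest.raises(ValueError, match="4x"):
            ed.SyntheticSpec(fs=100.0, carrier_freqs=(2.5, 6.0, 40.0))

    def test_unknown_state(self):
        with pytest.raises(ValueError, match="state"):
            ed.SyntheticSpec(duration_s=10.0, fs=1000.0,
                             state_schedule=(("rem", 10.0),))

    def test_band_lookup(self):
        assert band_of(2.5) == "delta"
        assert band_of(40.0) == "gamma"


class TestRecording:
    def test_schedule_conservation(self, scheduled_recording):
        rec, truth = scheduled_recording
        assert truth.epoch_states.count("rest") == 40
        assert truth.epoch_states.count("sws") == 10
        assert len(truth.epoch_states) == 50

    def test_recording_determinism(self):
        spec = ed.SyntheticSpec(duration_s=30.0, fs=500.0,
                                state_schedule=(("rest", 30.0),), seed=3)
        r1, t1 = ed.generate_recording(spec)
        r2, t2 = ed.generate_recording(spec)
        assert np.array_equal(r1.signals, r2.signals, equal_nan=True)
        assert t1.to_json() == t2.to_json()

    def test_explicit_gaps_annotated(self):
        gaps = ((12.0, 0.020), (33.0, 0.020), (71.0, 0.020))
        spec = ed.SyntheticSpec(duration_s=100.0, fs=500.0,
                                state_schedule=(("rest", 100.0),),
                                explicit_gaps=gaps, seed=1)
        rec, truth = ed.generate_recording(spec)
        assert rec.gaps == [tuple(g) for g in gaps]
        epochs_with_gap = {int(s // 5.0) for s, _ in rec.gaps}
        assert len(epochs_with_gap) == 3
        assert np.isnan(rec.signals[0, int(12.0 * 500)])

    def test_channel_layout_and_streams(self, scheduled_recording):
        rec, _ = scheduled_recording
        roles = [ch.role for ch in rec.channels]
        assert roles == ["frontal", "temporal_A1", "temporal_V1", "emg"]
        assert rec.sync_pulses.tolist() == [60.0, 120.0, 180.0, 240.0]

    def test_sws_elevates_frontal_delta(self, scheduled_recording):
        from scipy import signal as sg
        rec, truth = scheduled_recording
        sos = sg.butter(4, [0.5, 4.0], btype="band", fs=rec.fs, output="sos")
        delta = np.abs(sg.hilbert(sg.sosfiltfilt(sos, rec.get("frontal"))))
        ep = int(5 * rec.fs)
        amp = delta[: 50 * ep].reshape(50, ep).mean(axis=1)
        sws = [i for i, s in enumerate(truth.epoch_states) if s == "sws"]
        rest = [i for i, s in enumerate(truth.epoch_states) if s == "rest"]
        assert amp[sws].mean() > 3 * amp[rest].mean()


class TestPresets:
    def test_ko_preset_invariants(self):
        """Knockout preset: gamma power up, gamma Hurst up, gamma coupling
        negative relative to wild type."""
        base = ed.SyntheticSpec()
        wt = ed.PRESETS["WT"].apply(base)
        ko = ed.PRESETS["KO"].apply(base)
        gi = base.carrier_freqs.index(40.0)
        assert ko.carrier_amps[gi] > wt.carrier_amps[gi]
        assert ko.hurst[gi] > wt.hurst[gi]
        assert ko.coupling_kappa[gi] < wt.coupling_kappa[gi]
        assert ko.noise_floor[1] > wt.noise_floor[1]

    def test_cohort_gamma_power_contrast(self):
        """Generated KO cohort has higher mean gamma-band power than WT."""
        base = ed.SyntheticSpec(duration_s=40.0, fs=500.0,
                                state_schedule=(("rest", 40.0),))
        means = {}
        for name in ("WT", "KO"):
            vals = []
            for sid, _, rec, _ in ed.generate_cohort({name: 5}, base, seed=9):
                segs = [rec.signals[1]]  # A1
                ep = int(5 * rec.fs)
                epochs = segs[0][: (segs[0].size // ep) * ep].reshape(-1, ep)
                ps = ed.power_spectrum(epochs, rec.fs, "temporal")
                gamma = ps.power[(ps.freqs >= 30) & (ps.freqs <= 90)].mean()
                vals.append(gamma)
            means[name] = np.mean(vals)
        assert means["KO"] > means["WT"]

    def test_subject_seed_stable(self):
        assert subject_seed(123, 4) == subject_seed(123, 4)
        assert subject_seed(123, 4) != subject_seed(123, 5)
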