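"""Vigilance scoring, gap/artifact rules, and resting-segment extraction."""

import numpy as np
import pytest

import eegdyn as ed
from eegdyn.io import ChannelMeta, Recording
from eegdyn.resting import (EpochLabels, apply_gap_rules, extract_resting,
                            reject_artifacts, score_epochs)

import pandas as pd


def _labels(seq, n_rejected=0):
    n = len(seq)
    diag = pd.DataFrame({"delta_amp": np.zeros(n), "emg_rms": np.zeros(n),
                         "motion_count": np.zeros(n, int), "max_gap_ms": np.zeros(n)})
    return EpochLabels(labels=list(seq), diagnostics=diag, n_rejected_rest=n_rejected)


def _quiet_recording(fs=250.0, dur=50.0, gaps=(), seed=0):
    rng = np.random.default_rng(seed)
    n = int(dur * fs)
    sig = np.vstack([rng.normal(0, 10, size=(3, n)),
                     rng.normal(0, 5, size=(1, n))])
    for start, length in gaps:
        i0 = int(round(start * fs))
        i1 = max(i0 + 1, int(round((start + length) * fs)))
        sig[:, i0:i1] = np.nan
    return Recording(
        signals=sig, fs=fs,
        channels=[ChannelMeta("EEG Frontal", "frontal"),
                  ChannelMeta("EEG A1", "temporal_A1"),
                  ChannelMeta("EEG V1", "temporal_V1"),
                  ChannelMeta("EMG", "emg")],
        gaps=list(gaps),
    )


class TestScoring:
    def test_all_quiet_scores_rest(self):
        rec = _quiet_recording()
        labels = score_epochs(rec)
        assert set(labels.labels) == {"rest"}

    def test_rest_never_follows_sleep(self, scheduled_recording):
        """The first epoch after the slow-wave-sleep block is post_sleep."""
        rec, truth = scheduled_recording
        labels = score_epochs(rec)
        last_sws = max(i for i, s in enumerate(labels.labels) if s == "sws")
        assert labels.labels[last_sws + 1] == "post_sleep"
        for i in range(1, labels.n_epochs):
            assert not (labels.labels[i] == "rest" and labels.labels[i - 1] == "sws")

    def test_agreement_with_ground_truth(self):
        """Default thresholds recover >= 95% of scripted epoch labels."""
        spec = ed.SyntheticSpec(
            duration_s=600.0, fs=500.0,
            state_schedule=(("rest", 150.0), ("sws", 60.0), ("rest", 100.0),
                            ("active", 90.0), ("rest", 200.0)),
            seed=11,
        )
        rec, truth = ed.generate_recording(spec)
        labels = score_epochs(rec)
        expected = truth.expected_labels()
        agree = np.mean([a == b for a, b in zip(labels.labels, expected)])
        assert agree >= 0.95
        # rest recall and precision against ground truth
        tp = sum(1 for a, b in zip(labels.labels, expected) if a == b == "rest")
        recall = tp / expected.count("rest")
        precision = tp / labels.labels.count("rest")
        assert recall >= 0.95 and precision >= 0.95

    def test_motion_event_forces_active(self):
        rec = _quiet_recording()
        rec.motion_events = np.array([12.0])
        labels = score_epochs(rec)
        assert labels.labels[2] == "active"
        assert labels.labels[0] == "rest"

    def test_missing_channel(self):
        rec = _quiet_recording()
        rec.channels[3] = ChannelMeta("x", "reference")
        with pytest.raises(ValueError, match="emg"):
            score_epochs(rec)

    def test_label_partition(self, scheduled_recording):
        rec, _ = scheduled_recording
        labels = score_epochs(rec)
        assert sum(labels.counts().values()) == labels.n_epochs


class TestGapRules:
    @pytest.mark.parametrize("gap_ms,expect", [(8, "rest"), (10, "rest"),
                                               (20, "signal_loss")])
    def test_gap_boundary(self, gap_ms, expect):
        """Gaps of 8/10/20 ms produce interpolate/interpolate/exclude."""
        rec = _quiet_recording(gaps=[(12.0, gap_ms / 1000.0)])
        labels = _labels(["rest"] * 10)
        rec2, out = apply_gap_rules(rec, labels)
        assert out.labels[2] == expect
        assert all(l == "rest" for i, l in enumerate(out.labels) if i != 2)
        if expect == "rest":
            assert not np.isnan(rec2.signals).any()

    def test_interpolation_is_linear(self):
        """An 8-ms gap over a linear ramp is reconstructed exactly."""
        fs = 1000.0
        n = int(10 * fs)
        ramp = np.linspace(0.0, 100.0, n)
        sig = np.tile(ramp, (4, 1))
        gap = (4.0, 0.008)
        i0, i1 = int(4.0 * fs), int(4.008 * fs)
        sig[:, i0:i1] = np.nan
        rec = Recording(signals=sig, fs=fs,
                        channels=[ChannelMeta("EEG Frontal", "frontal"),
                                  ChannelMeta("EEG A1", "temporal_A1"),
                                  ChannelMeta("EEG V1", "temporal_V1"),
                                  ChannelMeta("EMG", "emg")],
                        gaps=[gap])
        rec2, _ = apply_gap_rules(rec, _labels(["rest"] * 2))
        assert np.allclose(rec2.signals[0], ramp, atol=1e-9)

    def test_boundary_gap_excluded(self):
        rec = _quiet_recording(gaps=[(0.0, 0.008)])
        _, out = apply_gap_rules(rec, _labels(["rest"] * 10))
        assert out.labels[0] == "signal_loss"


class TestArtifacts:
    def test_planted_artifact_epoch_flagged(self):
        """A 10x-SD half-sine transient flags exactly its epoch."""
        spec = ed.SyntheticSpec(duration_s=100.0, fs=500.0,
                                state_schedule=(("rest", 100.0),),
                                explicit_artifacts=(42.0,), seed=5)
        rec, truth = ed.generate_recording(spec)
        labels = score_epochs(rec)
        out = reject_artifacts(rec, labels)
        assert out.labels[8] == "artifact"
        assert out.labels.count("artifact") == 1

    def test_clean_recording_untouched(self):
        spec = ed.SyntheticSpec(duration_s=100.0, fs=500.0,
                                state_schedule=(("rest", 100.0),), seed=6)
        rec, _ = ed.generate_recording(spec)
        labels = score_epochs(rec)
        out = reject_artifacts(rec, labels)
        assert out.labels.count("artifact") == 0

    def test_all_artifact_recording_not_included(self):
        """When every rest epoch is rejected, the inclusion flag is false
        (rejection fraction above one half)."""
        spec = ed.SyntheticSpec(duration_s=100.0, fs=500.0,
                                state_schedule=(("rest", 100.0),),
                                explicit_artifacts=tuple(2.0 + 5.0 * i for i in range(20)),
                                seed=7)
        rec, _ = ed.generate_recording(spec)
        labels = score_epochs(rec)
        out = reject_artifacts(rec, labels)
        segset = extract_resting(out)
        assert segset.rejected_fraction > 0.5
        assert not segset.included


class TestExtractResting:
    def test_55_epochs_is_275_s(self):
        labels = _labels(["rest"] * 55 + ["active"] * 5)
        segset = extract_resting(labels)
        assert segset.n_epochs == 55
        assert segset.total_s == 275.0
        assert segset.included

    def test_75_s_not_included(self):
        labels = _labels(["rest"] * 15 + ["active"] * 10)
        segset = extract_resting(labels)
        assert segset.total_s == 75.0
        assert not segset.included

    def test_alternating_gives_single_epoch_segments(self):
        labels = _labels(["rest", "active"] * 20)
        segset = extract_resting(labels)
        assert len(segset.segments) == 20
        assert all(e - s == 5.0 for s, e in segset.segments)

    def test_bed_export(self):
        labels = _labels(["rest", "rest", "active", "rest"])
        bed = extract_resting(labels).to_bed()
        assert bed == "rest\t0\t10\nrest\t15\t20\n"

    def test_totals_are_consistent(self):
        labels = _labels(["rest"] * 10 + ["sws"] * 3 + ["post_sleep"] +
                         ["rest"] * 7 + ["artifact"] * 2, n_rejected=2)
        segset = extract_resting(labels)
        assert segset.total_s == sum(e - s for s, e in segset.segments)
        assert segset.n_epochs == 17
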