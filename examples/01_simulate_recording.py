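"""Simulate a rodent EEG recording with a scripted vigilance schedule.

Builds a five-minute, four-channel recording (frontal EEG, two temporal
EEG, EMG) containing rest, slow-wave sleep and active-movement blocks,
plus transmitter gaps and one high-amplitude artifact, and prints what was
planted.  The ground-truth sidecar is what every downstream stage is
tested against.
"""

import numpy as np

import eegdyn as ed

spec = ed.SyntheticSpec(
    duration_s=300.0,
    fs=500.0,
    state_schedule=(("rest", 120.0), ("sws", 60.0), ("rest", 60.0),
                    ("active", 30.0), ("rest", 30.0)),
    gap_rate=0.6,          # transmitter dropouts per minute
    explicit_artifacts=(200.0,),
    seed=42,
)
rec, truth = ed.generate_recording(spec, preset=ed.PRESETS["WT"])

print(f"channels: {[c.name for c in rec.channels]}")
print(f"duration: {rec.duration_s:.0f} s at {rec.fs:.0f} Hz")
print(f"sync pulses at: {rec.sync_pulses.tolist()} s")
print(f"motion events during active block: {rec.motion_events.size}")
print(f"gaps planted: {len(rec.gaps)} "
      f"(lengths {[round(1000 * l, 1) for _, l in rec.gaps]} ms)")
counts = {s: truth.epoch_states.count(s) for s in ("rest", "sws", "active")}
print(f"scheduled 5-s epochs: {counts}")
print(f"artifact planted in epoch {truth.artifact_epochs}")
# Interpretation: 42 rest + 12 sws + 6 active epochs cover the 300 s; the
# sidecar (truth) records exactly which epochs a perfect scorer should keep.
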