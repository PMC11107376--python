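"""Group difference waves with bootstrap confidence bands.

Simulates a small WT-vs-KO cohort, runs the full analysis (score, power,
DFA, fEI per 1-Hz bin) and reports the frequency ranges where the
confidence band of the group difference excludes zero — the decision rule
used for spectrum-wide comparisons.

Runs in a few minutes; shrink the cohort for a quicker look.
"""

import tempfile
from pathlib import Path

from eegdyn.pipeline import analyze_cohort, compare_groups, simulate_cohort

sim = {"duration_s": 240.0, "fs": 500.0,
       "state_schedule": [["rest", 150.0], ["active", 30.0], ["rest", 60.0]]}

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    simulate_cohort(tmp / "cohort", {"WT": 6, "KO": 6}, seed=77,
                    spec_overrides=sim)
    analyze_cohort(tmp / "cohort", tmp / "analysis", channel_groups=("temporal",))
    design = {f"WT_{i:02d}": "WT" for i in range(1, 7)}
    design.update({f"KO_{i:02d}": "KO" for i in range(1, 7)})
    # the sup-t "simultaneous" band controls the error rate over the whole
    # spectrum, so planted-contrast ranges stand out without scattered
    # single-bin false positives
    results = compare_groups(tmp / "analysis", tmp / "cmp", design,
                             metrics=("power", "fei"), seed=99, n_boot=1000,
                             family="simultaneous")

for metric, waves in results.items():
    w = waves[0]
    ranges = ", ".join(f"{lo}-{hi} Hz" for lo, hi in w.significant_ranges) or "none"
    print(f"{metric} ({w.label}, {w.level:.0%} band): significant at {ranges}")
# Interpretation: the knockout preset plants higher power (broadband plus a
# gamma oscillation) and a negative gamma coupling, so the power difference
# is positive across the spectrum and the fEI difference is negative around
# the 40-Hz carrier; bins outside the planted structure stay inside the band.
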