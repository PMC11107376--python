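"""End-to-end orchestration: simulate → score → analyze → compare.

These functions are the library behind the command-line interface; they
work on directories of recordings (EDF or delimited + JSON sidecars) and
produce tidy CSV tables.  Every excluded subject or epoch gets a
machine-readable reason code in the exclusion log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from . import resting, spectral
from .envelope import BandScheme, metric_spectrum
from .group import compare_conditions, difference_wave
from .resting import ScoringThresholds
from .synth import SyntheticSpec, write_cohort

log = logging.getLogger("eegdyn")

__all__ = [
    "simulate_cohort",
    "score_recording",
    "analyze_subject",
    "analyze_cohort",
    "compare_groups",
]

EPOCH_S = 5.0


def simulate_cohort(out_dir: str | Path, groups: dict[str, int], seed: int,
                    spec_overrides: dict | None = None, dialect: str = "edf") -> list[Path]:
    """Write a synthetic cohort (one recording per subject plus ground truth)."""
    fields = {f.name for f in dataclasses.fields(SyntheticSpec)}
    overrides = {k: v for k, v in (spec_overrides or {}).items() if k in fields}
    unknown = set(spec_overrides or {}) - fields
    if unknown:
        raise ValueError(f"unknown SyntheticSpec fields: {sorted(unknown)}")

    def _tup(v):
        return tuple(tuple(x) if isinstance(x, list) else x for x in v) \
            if isinstance(v, list) else v

    spec = SyntheticSpec(**{k: _tup(v) for k, v in overrides.items()})
    return write_cohort(out_dir, groups, spec, seed, dialect=dialect)


def score_recording(rec: rio.Recording, thresholds: ScoringThresholds = ScoringThresholds()
                    ) -> tuple[rio.Recording, resting.EpochLabels, resting.RestingSegmentSet]:
    """Score, apply gap and artifact rules, and extract resting segments."""
    labels = resting.score_epochs(rec, thresholds)
    rec2, labels = resting.apply_gap_rules(rec, labels)
    labels = resting.reject_artifacts(rec2, labels, thresholds)
    segset = resting.extract_resting(labels)
    return rec2, labels, segset


def analyze_subject(
    rec: rio.Recording,
    subject: str,
    scheme: BandScheme = BandScheme(),
    thresholds: ScoringThresholds = ScoringThresholds(),
    channel_groups: tuple[str, ...] = ("temporal", "frontal"),
) -> dict[str, pd.DataFrame] | str:
    """Power / DFA / fEI tables for one subject, or an exclusion reason code.

    Returns ``"below_min_rest"`` / ``"rejection_over_half"`` when the
    recording fails the a-priori inclusion thresholds (at least 80 s of
    resting-state signal; at most half the resting data rejected).
    """
    rec2, labels, segset = score_recording(rec, thresholds)
    if not segset.included:
        return ("below_min_rest" if segset.total_s < resting.MIN_REST_S
                else "rejection_over_half")
    power_rows, metric_rows = [], []
    ep = int(round(EPOCH_S * rec2.fs))
    for group in channel_groups:
        role = "frontal" if group == "frontal" else "temporal"
        segs = resting.resting_segments_signal(rec2, segset, role)
        epochs = np.concatenate(
            [s[: (s.size // ep) * ep].reshape(-1, ep) for s in segs if s.size >= ep])
        ps = spectral.power_spectrum(epochs, rec2.fs, group)
        power_rows.append(ps.to_frame(subject))
        ms = metric_spectrum(segs, rec2.fs, group, scheme)
        metric_rows.append(ms.to_frame(subject))
    metrics = pd.concat(metric_rows, ignore_index=True)
    return {
        "power": pd.concat(power_rows, ignore_index=True),
        "dfa": metrics[["subject", "freq_bin", "channel_group", "dfa_exponent"]].copy(),
        "fei": metrics[["subject", "freq_bin", "channel_group", "fei", "valid",
                        "n_windows_used", "n_outliers_removed"]].copy(),
        "rest": pd.DataFrame([{
            "subject": subject, "n_rest_epochs": segset.n_epochs,
            "total_rest_s": segset.total_s,
            "rejected_fraction": segset.rejected_fraction,
        }]),
    }


def analyze_cohort(
    in_dir: str | Path,
    out_dir: str | Path,
    scheme: BandScheme = BandScheme(),
    thresholds: ScoringThresholds = ScoringThresholds(),
    channel_groups: tuple[str, ...] = ("temporal", "frontal"),
) -> dict[str, Path]:
    """Run the analysis over every recording in ``in_dir``; write CSVs.

    Produces ``power.csv``, ``dfa.csv``, ``fei.csv``, ``rest.csv`` and
    ``exclusions.csv`` in ``out_dir``.  Raises ``RuntimeError`` when no
    subject passes the inclusion thresholds.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = sorted(list(in_dir.glob("*.edf")) + list(in_dir.glob("*.csv")))
    tables: dict[str, list[pd.DataFrame]] = {"power": [], "dfa": [], "fei": [], "rest": []}
    exclusions = []
    for path in files:
        subject = path.stem
        rec = rio.read_recording(path)
        rec = rio.downsample(rec, min(1000.0, rec.fs))
        result = analyze_subject(rec, subject, scheme, thresholds, channel_groups)
        if isinstance(result, str):
            log.warning("excluding %s: %s", subject, result)
            exclusions.append({"subject": subject, "reason": result})
            continue
        for k in tables:
            tables[k].append(result[k])
    if not tables["power"]:
        raise RuntimeError("no includable subjects")
    out = {}
    for k, frames in tables.items():
        p = out_dir / f"{k}.csv"
        pd.concat(frames, ignore_index=True).to_csv(p, index=False)
        out[k] = p
    p = out_dir / "exclusions.csv"
    pd.DataFrame(exclusions, columns=["subject", "reason"]).to_csv(p, index=False)
    out["exclusions"] = p
    return out


def _metric_frame(analysis_dir: Path, metric: str) -> tuple[pd.DataFrame, str]:
    df = pd.read_csv(analysis_dir / f"{metric}.csv")
    col = {"power": "power", "dfa": "dfa_exponent", "fei": "fei"}[metric]
    if metric == "fei":
        df.loc[~df["valid"].astype(bool), "fei"] = np.nan
    return df, col


def compare_groups(
    analysis_dir: str | Path,
    out_dir: str | Path,
    design: dict[str, str],
    metrics: tuple[str, ...] = ("power", "dfa", "fei"),
    channel_group: str = "temporal",
    baseline: str | None = None,
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int | None = None,
    smooth: bool = False,
    family: str = "pointwise",
) -> dict[str, list]:
    """Difference waves per metric between the designs' groups.

    ``design`` maps subject id → group/condition name.  With two groups a
    single contrast at the 95% level is computed (first-listed group minus
    the other); with ``baseline`` given, every other condition is compared
    against it at the Bonferroni-widened level.  Results go to CSV + a JSON
    summary of significant ranges.
    """
    analysis_dir, out_dir = Path(analysis_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict[str, list] = {}
    summary = {}
    for metric in metrics:
        df, col = _metric_frame(analysis_dir, metric)
        df = df[df["channel_group"] == channel_group]
        missing = sorted(set(df["subject"].unique()) - set(design))
        if missing:
            raise ValueError(f"design missing subjects: {missing}")
        df = df.assign(group=df["subject"].map(design))
        by_group: dict[str, dict[str, np.ndarray]] = {}
        for (g, s), sub in df.groupby(["group", "subject"]):
            vals = sub.sort_values("freq_bin")[col].to_numpy(dtype=float)
            by_group.setdefault(g, {})[s] = vals
        if len(by_group) < 2:
            raise ValueError("need at least two groups/conditions in the design")
        if baseline is not None:
            waves = compare_conditions(by_group, baseline, alpha=alpha, seed=seed,
                                       n_boot=n_boot, smooth=smooth, family=family)
        else:
            names = sorted(by_group)
            if len(names) != 2:
                raise ValueError("without a baseline, exactly two groups are expected")
            waves = [difference_wave(by_group[names[0]], by_group[names[1]],
                                     level=1 - alpha, seed=seed, n_boot=n_boot,
                                     smooth=smooth, family=family,
                                     label=f"{names[0]} - {names[1]}")]
        results[metric] = waves
        for w in waves:
            tag = f"{metric}__{w.label.split(' (')[0].replace(' ', '')}"
            w.to_frame().to_csv(out_dir / f"{tag}.csv", index=False)
            summary[tag] = {
                "level": w.level,
                "significant_ranges": [list(r) for r in w.significant_ranges],
                "n_subjects": list(w.n_subjects),
            }
    (out_dir / "ranges.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return results
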