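"""Group and condition comparison of per-frequency spectra.

The decision rule follows the convention of smoothed difference curves:
frequency ranges where the confidence band of the group-difference wave
excludes zero are called significant.  For a single contrast a 95% band is
used (α = 0.05); for k simultaneous contrasts the level is Bonferroni
widened to 1 − α/k (e.g. 98.3% for a triple comparison, α = 0.0167 each).

Bands come from a subject-level bootstrap: subjects are resampled with
replacement within group, the per-bin group-mean difference recomputed per
draw, and a percentile band taken.  Resampling whole subjects preserves the
within-spectrum correlation across neighboring frequency bins, which is
what parametric spectrum models must otherwise correct for explicitly.
``family="simultaneous"`` additionally calibrates a sup-t band so the error
rate is controlled over the whole spectrum rather than per bin.

An optional discrete penalized smoother (second-difference ridge with
GCV-chosen penalty) can be applied to each draw, mirroring smooth fitted
spectra for display; it is off by default and off in coverage checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DifferenceWave",
    "ci_level_for_comparisons",
    "difference_wave",
    "compare_conditions",
    "gcv_smooth",
]


def ci_level_for_comparisons(alpha: float, k: int) -> float:
    """Bonferroni-widened confidence level for k comparisons: 1 − alpha/k."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if k < 1 or int(k) != k:
        raise ValueError("k must be a positive integer")
    return 1.0 - alpha / k


@dataclass
class DifferenceWave:
    """Per-frequency group difference with its confidence band."""

    freqs: np.ndarray
    delta: np.ndarray           #: group A − group B per bin (NaN: indeterminate)
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    level: float
    significant_ranges: list[tuple[int, int]]  #: inclusive integer-frequency intervals
    n_subjects: tuple[int, int] = (0, 0)
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        sig = np.zeros(self.freqs.size, dtype=int)
        for lo, hi in self.significant_ranges:
            sig[(self.freqs >= lo) & (self.freqs <= hi)] = 1
        return pd.DataFrame({
            "freq_bin": self.freqs.astype(int),
            "delta": self.delta,
            "ci_lo": self.ci_lo,
            "ci_hi": self.ci_hi,
            "significant": sig,
        })


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def _second_diff_eig(n: int) -> tuple[np.ndarray, np.ndarray]:
    d2 = np.zeros((n - 2, n))
    for i in range(n - 2):
        d2[i, i:i + 3] = (1.0, -2.0, 1.0)
    k = d2.T @ d2
    w, u = np.linalg.eigh(k)
    return w, u


def gcv_smooth(y: np.ndarray, lam: float | None = None) -> tuple[np.ndarray, float]:
    """Penalized (second-difference ridge) smoother over the frequency axis.

    Solves min ||y − f||² + λ Σ (Δ²f)², with λ chosen by generalized
    cross-validation when not given.  Returns (smoothed, λ).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    w, u = _second_diff_eig(n)
    yt = u.T @ y
    if lam is None:
        lams = np.logspace(-2, 4, 25)
        best, best_score = lams[0], np.inf
        for L in lams:
            shrink = 1.0 / (1.0 + L * w)
            resid = yt * (1 - shrink)
            tr = shrink.sum()
            denom = (1 - tr / n) ** 2
            score = (resid @ resid) / n / denom if denom > 0 else np.inf
            if score < best_score:
                best, best_score = L, score
        lam = float(best)
    fhat = u @ (yt / (1.0 + lam * w))
    return fhat, lam


# ---------------------------------------------------------------------------
# difference waves
# ---------------------------------------------------------------------------

def _group_matrix(spectra: dict[str, np.ndarray] | pd.DataFrame, value_col: str | None
                  ) -> np.ndarray:
    if isinstance(spectra, pd.DataFrame):
        if value_col is None:
            raise ValueError("value_col required with a DataFrame input")
        wide = spectra.pivot_table(index="subject", columns="freq_bin",
                                   values=value_col, dropna=False)
        return wide.to_numpy(dtype=float)
    return np.vstack([np.asarray(v, dtype=float) for v in spectra.values()])


def _ranges_from_mask(freqs: np.ndarray, mask: np.ndarray) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    start = None
    for f, m in zip(freqs, mask):
        if m and start is None:
            start = int(f)
        elif not m and start is not None:
            out.append((start, int(f) - 1))
            start = None
    if start is not None:
        out.append((start, int(freqs[-1])))
    return out


def difference_wave(
    spectra_a,
    spectra_b,
    level: float = 0.95,
    smooth: bool = False,
    n_boot: int = 2000,
    seed: int | None = None,
    freqs: np.ndarray | None = None,
    value_col: str | None = None,
    min_subjects: int = 3,
    family: str = "pointwise",
    label: str = "",
) -> DifferenceWave:
    """Bootstrap difference wave (group A − group B) with confidence band.

    ``spectra_a`` / ``spectra_b`` are either dicts ``{subject: values}`` (one
    value per frequency bin, NaN where the bin is unavailable, e.g. gated
    fEI) or tidy DataFrames with subject / freq_bin / ``value_col`` columns.
    Bins with fewer than ``min_subjects`` finite values in either group are
    indeterminate (NaN, never significant).  A seed is required: the band is
    a Monte-Carlo quantity and runs must be reproducible.
    """
    if seed is None:
        raise ValueError("a seed is required for the bootstrap")
    a = _group_matrix(spectra_a, value_col)
    b = _group_matrix(spectra_b, value_col)
    if a.shape[0] < min_subjects or b.shape[0] < min_subjects:
        raise ValueError(f"need at least {min_subjects} subjects per group")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the frequency grid")
    nf = a.shape[1]
    if freqs is None:
        freqs = np.arange(1, nf + 1)
    freqs = np.asarray(freqs)

    ok = (np.sum(np.isfinite(a), axis=0) >= min_subjects) & \
         (np.sum(np.isfinite(b), axis=0) >= min_subjects)
    if not ok.any():
        raise ValueError("all bins indeterminate")

    def mean_diff(am: np.ndarray, bm: np.ndarray) -> np.ndarray:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            d = np.nanmean(am, axis=0) - np.nanmean(bm, axis=0)
        d[~ok] = np.nan
        return d

    delta = mean_diff(a, b)
    lam = None
    if smooth:
        fin = np.isfinite(delta)
        sm, lam = gcv_smooth(delta[fin])
        delta = delta.copy()
        delta[fin] = sm

    rng = np.random.default_rng(seed)
    with np.errstate(invalid="ignore"):
        if family == "simultaneous":
            # Studentized permutation sup-test: controls the family-wise
            # error over the whole spectrum even at small group sizes,
            # where bootstrap percentile bands undercover badly (per-bin
            # statistics have t-tails the bootstrap cannot reproduce).
            def _se(am, bm):
                import warnings
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    na_ = np.sum(np.isfinite(am), axis=0)
                    nb_ = np.sum(np.isfinite(bm), axis=0)
                    va = np.where(na_ > 1, np.nanvar(am, axis=0, ddof=1), np.nan) / na_
                    vb = np.where(nb_ > 1, np.nanvar(bm, axis=0, ddof=1), np.nan) / nb_
                return np.sqrt(va + vb)

            pooled = np.vstack([a, b])
            na = a.shape[0]
            sups = np.empty(n_boot)
            for i in range(n_boot):
                perm = rng.permutation(pooled.shape[0])
                ap, bp = pooled[perm[:na]], pooled[perm[na:]]
                t = mean_diff(ap, bp) / _se(ap, bp)
                t = np.where(np.isfinite(t), np.abs(t), -np.inf)
                sups[i] = t.max()
            c = float(np.quantile(sups, level))
            se = _se(a, b)
            lo = delta - c * se
            hi = delta + c * se
        else:
            draws = np.empty((n_boot, nf))
            for i in range(n_boot):
                ia = rng.integers(0, a.shape[0], a.shape[0])
                ib = rng.integers(0, b.shape[0], b.shape[0])
                d = mean_diff(a[ia], b[ib])
                if smooth:
                    fin = np.isfinite(d)
                    if fin.sum() >= 5:
                        d[fin] = gcv_smooth(d[fin], lam)[0]
                draws[i] = d
            q = (1.0 - level) / 2.0
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                lo = np.nanquantile(draws, q, axis=0)
                hi = np.nanquantile(draws, 1.0 - q, axis=0)
    lo = np.where(ok, lo, np.nan)
    hi = np.where(ok, hi, np.nan)
    with np.errstate(invalid="ignore"):
        sig = ok & np.isfinite(lo) & np.isfinite(hi) & ((lo > 0) | (hi < 0))
    return DifferenceWave(
        freqs=freqs, delta=delta, ci_lo=lo, ci_hi=hi, level=level,
        significant_ranges=_ranges_from_mask(freqs, sig),
        n_subjects=(a.shape[0], b.shape[0]), label=label,
    )


def compare_conditions(
    spectra_by_condition: dict[str, dict[str, np.ndarray]],
    baseline: str,
    alpha: float = 0.05,
    seed: int | None = None,
    **kwargs,
) -> list[DifferenceWave]:
    """One difference wave per non-baseline condition against the baseline.

    The confidence level is Bonferroni widened for the number of comparisons
    (three non-baseline conditions → 98.3% bands each).  Subjects absent
    from either condition are dropped; the count of unmatched subjects is
    recorded in ``DifferenceWave.label``.
    """
    if baseline not in spectra_by_condition:
        raise ValueError(f"baseline condition {baseline!r} missing")
    others = [c for c in spectra_by_condition if c != baseline]
    if not others:
        raise ValueError("need at least one non-baseline condition")
    level = ci_level_for_comparisons(alpha, len(others))
    base = spectra_by_condition[baseline]
    out = []
    for cond in others:
        cur = spectra_by_condition[cond]
        shared = sorted(set(base) & set(cur))
        dropped = len(set(base) ^ set(cur))
        wave = difference_wave(
            {s: cur[s] for s in shared},
            {s: base[s] for s in shared},
            level=level,
            seed=seed,
            label=f"{cond} - {baseline}" + (f" ({dropped} unmatched dropped)" if dropped else ""),
            **kwargs,
        )
        out.append(wave)
    return out
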