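"""Small statistical utilities: the generalized ESD outlier test."""

from __future__ import annotations

import numpy as np
from scipy import stats as _st

__all__ = ["generalized_esd"]


def generalized_esd(x, max_outliers: int, alpha: float = 0.05) -> np.ndarray:
    """Two-sided generalized extreme studentized deviate (ESD) test.

    Iteratively removes the most extreme studentized value up to
    ``max_outliers`` times and compares each test statistic R_i against its
    critical value lambda_i; the declared outliers are the first i_max removed
    points, where i_max is the largest i with R_i > lambda_i (Rosner's
    procedure for an approximately normal sample with an unknown number of
    outliers).

    Returns the indices of the declared outliers (possibly empty).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if max_outliers < 1 or max_outliers >= n - 1:
        max_outliers = max(1, min(max_outliers, n - 2))
    if n < 3:
        return np.empty(0, dtype=int)

    # critical values lambda_i for every step, in one vectorized ppf call
    i = np.arange(1, max_outliers + 1)
    m = n - i + 1  # sample size at step i
    t = _st.t.ppf(1 - alpha / (2 * m), m - 2)
    lam = (m - 1) * t / np.sqrt((m - 2 + t * t) * m)

    active = np.arange(n)
    vals = x.copy()
    removed: list[int] = []
    n_signif = 0
    for step in range(max_outliers):
        mu = vals.mean()
        sd = vals.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            break
        dev = np.abs(vals - mu)
        j = int(np.argmax(dev))
        removed.append(int(active[j]))
        if dev[j] / sd > lam[step]:
            n_signif = step + 1
        active = np.delete(active, j)
        vals = np.delete(vals, j)
    return np.asarray(removed[:n_signif], dtype=int)
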