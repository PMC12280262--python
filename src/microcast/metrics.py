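"""Forecast error and time-series diagnostics.

Three diagnostics summarise each series: the coefficient of variation
(SD of the detrended series over the mean of the original series — temporal
variability), the lag-5 autocorrelation (memory), and normalized permutation
entropy (ordinal-pattern complexity). Autocorrelation and permutation entropy
are computed on the transformed (detrended, standardized) series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TSMetrics:
    cv: float
    ac5: float
    pe: float
    pe_order: int = 3


def rmse(predictions, observations) -> float:
    """Root mean square error, sqrt(mean((p - o)^2))."""
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    if p.size == 0:
        raise ValueError("need at least one point")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def coefficient_of_variation(detrended, original) -> float:
    """SD of the detrended residuals over the mean of the original series.

    The residuals enter before standardization (after division by their SD
    the ratio would be 1/mean identically).
    """
    d = np.asarray(detrended, dtype=float)
    x = np.asarray(original, dtype=float)
    mean = float(np.mean(x))
    if mean == 0.0:
        raise ValueError("zero mean original series: CV undefined")
    sd = float(np.sqrt(np.mean((d - d.mean()) ** 2)))
    return sd / mean


def autocorrelation(x, lag: int = 5) -> float:
    """Pearson correlation of (x_t, x_{t-lag}) over the overlapping window."""
    x = np.asarray(x, dtype=float)
    if len(x) <= lag + 2:
        raise ValueError(f"series of length {len(x)} too short for lag {lag}")
    if lag == 0:
        return 1.0
    a, b = x[lag:], x[:-lag]
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        raise ValueError("zero variance in a lag window")
    return float(np.corrcoef(a, b)[0, 1])


def _ordinal_pattern(window: np.ndarray) -> tuple[int, ...]:
    # rank permutation; ties broken by temporal order (stable argsort)
    return tuple(np.argsort(window, kind="stable"))


def permutation_entropy(x, m: int = 3) -> float:
    """Normalized permutation entropy of order m, in [0, 1].

    Slides a window of length m over the series, maps each window to its
    ordinal (rank) pattern with ties broken by temporal order, and computes
    the Shannon entropy of the pattern distribution normalized by ln(m!).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < m + 1:
        raise ValueError(f"series of length {n} shorter than order {m} + 1")
    counts: dict[tuple[int, ...], int] = {}
    for i in range(n - m + 1):
        pat = _ordinal_pattern(x[i:i + m])
        counts[pat] = counts.get(pat, 0) + 1
    total = sum(counts.values())
    h = -sum((c / total) * math.log(c / total) for c in counts.values())
    return h / math.log(math.factorial(m))


def ts_metrics(transformed_values, residuals, original, lag: int = 5,
               pe_order: int = 3) -> TSMetrics:
    """All three diagnostics for one series.

    ``transformed_values`` is the standardized series (for ac5 and PE),
    ``residuals`` the detrended-but-unstandardized series and ``original``
    the raw regridded series (for the CV).
    """
    return TSMetrics(
        cv=coefficient_of_variation(residuals, original),
        ac5=autocorrelation(transformed_values, lag=lag),
        pe=permutation_entropy(transformed_values, m=pe_order),
        pe_order=pe_order,
    )
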