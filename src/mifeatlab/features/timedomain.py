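"""Time-domain feature set: 24 amplitude/statistics descriptors per series.

Codes and definitions (sample statistics use the n-1 denominator):

========  =======================================================
T1 / T2   minimum / maximum value
T3 / T4   mean / standard deviation
T5        integrated EEG, sum(|x|)
T6        mean absolute value
T7        simple square integral, sum(x^2)
T8        variance
T9        root mean square
T10       waveform length, sum(|diff(x)|)
T11       average amplitude change, T10 / (n-1)
T12       absolute difference of standard deviation,
          sqrt(sum(diff(x)^2) / (n-1))
T13/T14   kurtosis (non-excess, normal = 3) / skewness
T15-T17   Hjorth activity, mobility, complexity
T18       signal range, max - min
T19-T21   quartiles Q1/Q2/Q3 (linear interpolation)
T22       mode (histogram mode, 100 equal-width bins, bin center)
T23       zero-crossing count (strict sign change, dead-band eps)
T24       slope-change count (sign change of consecutive diffs)
========  =======================================================

A constant series has undefined Hjorth mobility/complexity and undefined
skewness/kurtosis; those entries come back NaN with a logged warning,
never an exception.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

TIME_FEATURE_CODES: tuple[str, ...] = tuple(f"T{i}" for i in range(1, 25))

__all__ = ["TIME_FEATURE_CODES", "extract_time_features", "time_feature_table"]


def _histogram_mode(X: np.ndarray, lo: np.ndarray, hi: np.ndarray, bins: int) -> np.ndarray:
    """Row-wise histogram mode: center of the most populated of `bins`
    equal-width bins over [min, max]; ties break toward the lowest bin."""
    R, n = X.shape
    width = hi - lo
    degenerate = width == 0
    safe_width = np.where(degenerate, 1.0, width)
    idx = np.floor((X - lo[:, None]) / safe_width[:, None] * bins).astype(np.int64)
    np.clip(idx, 0, bins - 1, out=idx)
    flat = (np.arange(R)[:, None] * bins + idx).ravel()
    counts = np.bincount(flat, minlength=R * bins).reshape(R, bins)
    best = counts.argmax(axis=1)
    mode = lo + (best + 0.5) * width / bins
    return np.where(degenerate, lo, mode)


def time_feature_table(
    X: np.ndarray,
    *,
    zc_threshold: float = 0.0,
    ssc_threshold: float = 0.0,
    mode_bins: int = 100,
) -> np.ndarray:
    """Compute T1..T24 for every row of ``X`` (shape ``(R, n)``), vectorized.

    Returns an ``(R, 24)`` array in code order.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    R, n = X.shape
    if n < 4:
        raise ValueError(f"series length must be >= 4, got {n}")
    if not np.isfinite(X).all():
        raise ValueError("input contains non-finite values")

    out = np.empty((R, 24))
    d = np.diff(X, axis=1)
    mn = X.min(axis=1)
    mx = X.max(axis=1)
    mean = X.mean(axis=1)
    var = X.var(axis=1, ddof=1)
    std = np.sqrt(var)

    out[:, 0] = mn
    out[:, 1] = mx
    out[:, 2] = mean
    out[:, 3] = std
    out[:, 4] = np.abs(X).sum(axis=1)
    out[:, 5] = np.abs(X).mean(axis=1)
    out[:, 6] = (X**2).sum(axis=1)
    out[:, 7] = var
    out[:, 8] = np.sqrt((X**2).mean(axis=1))
    wl = np.abs(d).sum(axis=1)
    out[:, 9] = wl
    out[:, 10] = wl / (n - 1)
    out[:, 11] = np.sqrt((d**2).sum(axis=1) / (n - 1))

    centered = X - mean[:, None]
    m2 = (centered**2).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out[:, 12] = (centered**4).mean(axis=1) / m2**2  # non-excess kurtosis
        out[:, 13] = (centered**3).mean(axis=1) / m2**1.5
        var_d = d.var(axis=1, ddof=1)
        var_dd = np.diff(d, axis=1).var(axis=1, ddof=1)
        mobility = np.sqrt(var_d / var)
        mobility_d = np.sqrt(var_dd / var_d)
        out[:, 14] = var  # Hjorth activity
        out[:, 15] = mobility
        out[:, 16] = mobility_d / mobility
    out[:, 17] = mx - mn
    out[:, 18:21] = np.percentile(X, [25, 50, 75], axis=1).T
    out[:, 21] = _histogram_mode(X, mn, mx, mode_bins)
    zc = (X[:, :-1] * X[:, 1:] < 0) & (np.abs(X[:, :-1] - X[:, 1:]) > zc_threshold)
    out[:, 22] = zc.sum(axis=1)
    ssc = (d[:, :-1] * d[:, 1:] < 0) & (
        np.maximum(np.abs(d[:, :-1]), np.abs(d[:, 1:])) > ssc_threshold
    )
    out[:, 23] = ssc.sum(axis=1)

    n_bad = int(np.count_nonzero(~np.isfinite(out[:, 15])))
    if n_bad:
        logger.warning(
            "Hjorth mobility/complexity undefined (constant input) for %d of %d series; "
            "emitting NaN",
            n_bad,
            R,
        )
    return out


def extract_time_features(x: np.ndarray, **kwargs) -> np.ndarray:
    """T1..T24 for a single channel-trial series (length >= 4, finite)."""
    return time_feature_table(np.asarray(x, dtype=np.float64)[None, :], **kwargs)[0]
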