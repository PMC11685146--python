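"""Lagged Poincaré-plot feature set: SD1/SD2 descriptors at lags 1 and 9.

A Poincaré plot scatters a series against its lag-m copy:
``x_i = (x_0, ..., x_{N-m})`` on the abscissa and
``x_lag = (x_m, ..., x_N)`` on the ordinate (N the last index).  Rotating
the cloud by 45 degrees,

    x_a = (x_lag - x_i) / sqrt(2),   x_b = (x_lag + x_i) / sqrt(2),

the minor/major axis dispersions of the fitted ellipse are
``SD1 = sd(x_a)`` and ``SD2 = sd(x_b)`` (sample standard deviation, n-1
denominator).  SD1 captures short-term (lag-scale) variability, SD2
long-term variability; their product and ratio complete the set.  Codes
P1..P4 are SD1, SD2, SD1*SD2, SD1/SD2 at lag 1 and P5..P8 the same at
lag 9.

When SD2 = 0 (constant series) the ratio is NaN with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

POINCARE_FEATURE_CODES: tuple[str, ...] = tuple(f"P{i}" for i in range(1, 9))

DEFAULT_LAGS: tuple[int, ...] = (1, 9)

__all__ = [
    "POINCARE_FEATURE_CODES",
    "DEFAULT_LAGS",
    "PoincareCloud",
    "PoincareMeasures",
    "poincare_cloud",
    "poincare_measures",
    "extract_poincare_features",
    "poincare_feature_table",
]


@dataclass
class PoincareCloud:
    """The lag-m scatter of a series and its 45-degree rotation."""

    x_i: np.ndarray
    x_lag: np.ndarray
    m: int

    @property
    def x_a(self) -> np.ndarray:
        return (self.x_lag - self.x_i) / np.sqrt(2.0)

    @property
    def x_b(self) -> np.ndarray:
        return (self.x_lag + self.x_i) / np.sqrt(2.0)


@dataclass
class PoincareMeasures:
    """Ellipse dispersions and their product/ratio for one lag."""

    SD1: float
    SD2: float
    product: float
    ratio: float
    m: int


def poincare_cloud(x: np.ndarray, m: int) -> PoincareCloud:
    """Build the lag-``m`` Poincaré cloud (requires ``len(x) > m + 1``)."""
    x = np.asarray(x, dtype=np.float64)
    if x.size <= m + 1:
        raise ValueError(f"series of length {x.size} too short for lag m={m}")
    return PoincareCloud(x_i=x[: x.size - m], x_lag=x[m:], m=m)


def poincare_measures(x: np.ndarray, m: int) -> PoincareMeasures:
    """SD1, SD2, SD1*SD2 and SD1/SD2 of the lag-``m`` Poincaré plot."""
    cloud = poincare_cloud(x, m)
    # exact zero for a constant projection (avoids fp residue of the mean)
    sd1 = 0.0 if np.ptp(cloud.x_a) == 0 else float(np.std(cloud.x_a, ddof=1))
    sd2 = 0.0 if np.ptp(cloud.x_b) == 0 else float(np.std(cloud.x_b, ddof=1))
    if sd2 == 0:
        logger.warning("SD2 = 0 at lag m=%d: SD1/SD2 undefined, emitting NaN", m)
        ratio = float("nan")
    else:
        ratio = sd1 / sd2
    return PoincareMeasures(SD1=sd1, SD2=sd2, product=sd1 * sd2, ratio=ratio, m=m)


def extract_poincare_features(x: np.ndarray, lags: tuple[int, ...] = DEFAULT_LAGS) -> np.ndarray:
    """P1..P8: [SD1, SD2, SD1*SD2, SD1/SD2] at each lag, in lag order."""
    x = np.asarray(x, dtype=np.float64)
    if x.size <= max(lags) + 1:
        raise ValueError(f"series of length {x.size} too short for lags {lags}")
    vals = []
    for m in lags:
        meas = poincare_measures(x, m)
        vals.extend([meas.SD1, meas.SD2, meas.product, meas.ratio])
    return np.asarray(vals)


def poincare_feature_table(
    X: np.ndarray, lags: tuple[int, ...] = DEFAULT_LAGS
) -> np.ndarray:
    """Vectorized P1..P8 for every row of ``X``; returns ``(R, 4 * len(lags))``."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    R, n = X.shape
    if n <= max(lags) + 1:
        raise ValueError(f"series length {n} too short for lags {lags}")
    out = np.empty((R, 4 * len(lags)))
    for j, m in enumerate(lags):
        xi = X[:, : n - m]
        xl = X[:, m:]
        xa = (xl - xi) / np.sqrt(2.0)
        xb = (xl + xi) / np.sqrt(2.0)
        sd1 = np.where(np.ptp(xa, axis=1) == 0, 0.0, np.std(xa, axis=1, ddof=1))
        sd2 = np.where(np.ptp(xb, axis=1) == 0, 0.0, np.std(xb, axis=1, ddof=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(sd2 > 0, sd1 / sd2, np.nan)
        if np.any(sd2 == 0):
            logger.warning(
                "SD2 = 0 at lag m=%d for %d series: SD1/SD2 undefined, emitting NaN",
                m, int(np.count_nonzero(sd2 == 0)),
            )
        out[:, 4 * j] = sd1
        out[:, 4 * j + 1] = sd2
        out[:, 4 * j + 2] = sd1 * sd2
        out[:, 4 * j + 3] = ratio
    return out
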