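"""Independent straight-from-definition oracles for the feature battery.

Every function here recomputes a quantity from its printed definition by a
route deliberately different from the library path: explicit Python loops
and `statistics`/`math` for the time-domain set, an explicit DFT matrix
(no FFT) for the spectral set, PyWavelets for the wavelet-packet set, and
permutation resampling for p-values.
"""

from __future__ import annotations

import math
import statistics

import numpy as np
import pywt
from scipy import signal as sp_signal


# ---------------------------------------------------------------- time domain
def _quartile(sorted_x: list[float], q: float) -> float:
    """Linear interpolation between order statistics (the 'linear' method)."""
    n = len(sorted_x)
    pos = (n - 1) * q
    lo = math.floor(pos)
    hi = math.ceil(pos)
    if lo == hi:
        return sorted_x[lo]
    frac = pos - lo
    return sorted_x[lo] * (1 - frac) + sorted_x[hi] * frac


def _var1(vals: list[float]) -> float:
    m = sum(vals) / len(vals)
    return sum((v - m) ** 2 for v in vals) / (len(vals) - 1)


def time_oracle(x, mode_bins: int = 100) -> list[float]:
    """T1..T24 by brute force."""
    x = [float(v) for v in x]
    n = len(x)
    d = [x[i + 1] - x[i] for i in range(n - 1)]
    dd = [d[i + 1] - d[i] for i in range(len(d) - 1)]
    mean = sum(x) / n
    var = _var1(x)
    sd = math.sqrt(var)
    mn, mx = min(x), max(x)

    m2 = sum((v - mean) ** 2 for v in x) / n
    if m2 > 0:
        kurt = (sum((v - mean) ** 4 for v in x) / n) / m2**2
        skew = (sum((v - mean) ** 3 for v in x) / n) / m2**1.5
    else:
        kurt = skew = float("nan")
    if var > 0 and _var1(d) > 0:
        mobility = math.sqrt(_var1(d) / var)
        complexity = math.sqrt(_var1(dd) / _var1(d)) / mobility
    else:
        mobility = complexity = float("nan")

    sx = sorted(x)
    if mx > mn:
        width = (mx - mn) / mode_bins
        counts = [0] * mode_bins
        for v in x:
            counts[min(int((v - mn) / (mx - mn) * mode_bins), mode_bins - 1)] += 1
        best = counts.index(max(counts))
        mode = mn + (best + 0.5) * width
    else:
        mode = mn
    zc = sum(1 for i in range(n - 1) if x[i] * x[i + 1] < 0)
    ssc = sum(1 for i in range(len(d) - 1) if d[i] * d[i + 1] < 0)

    return [
        mn, mx, mean, sd,
        sum(abs(v) for v in x),
        sum(abs(v) for v in x) / n,
        sum(v * v for v in x),
        var,
        math.sqrt(sum(v * v for v in x) / n),
        sum(abs(v) for v in d),
        sum(abs(v) for v in d) / (n - 1),
        math.sqrt(sum(v * v for v in d) / (n - 1)),
        kurt, skew,
        var, mobility, complexity,
        mx - mn,
        _quartile(sx, 0.25), _quartile(sx, 0.50), _quartile(sx, 0.75),
        mode, float(zc), float(ssc),
    ]


# ------------------------------------------------------------ spectral domain
def dft_matrix_oracle(n: int) -> np.ndarray:
    """One-sided DFT matrix (explicit exponentials; no FFT)."""
    k = np.arange(n // 2 + 1)[:, None]
    t = np.arange(n)[None, :]
    return np.exp(-2j * np.pi * k * t / n)


def spectral_oracle(x, fs: float, bands: dict[str, tuple[float, float]]) -> list[float]:
    """Energy/variance/entropy per band, verbatim from the printed formulas."""
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    y_full = dft_matrix_oracle(n) @ x
    freqs = np.arange(n // 2 + 1) * fs / n
    out = []
    for lo, hi in bands.values():
        y = y_full[(freqs >= lo) & (freqs < hi)]
        M = y.size
        energy = sum(abs(v) ** 2 for v in y)
        mags = [abs(v) for v in y]
        ybar = sum(mags) / M
        variance = sum((m - ybar) ** 2 for m in mags) / (M - 1) if M > 1 else float("nan")
        if energy > 0 and M > 1:
            P = [abs(v) ** 2 / energy for v in y]
            entropy = sum(p * math.log(p) for p in P if p > 0) / math.log(M)
        else:
            entropy = 0.0
        out.extend([energy, variance, entropy])
    return out


# ------------------------------------------------------------- wavelet domain
def pywt_packet_nodes(x, level: int = 7) -> np.ndarray:
    """Frequency-ordered terminal packet coefficients via PyWavelets."""
    x = np.asarray(x, dtype=np.float64)
    npad = 2**level
    while npad < x.size:
        npad *= 2
    padded = np.concatenate([x, np.zeros(npad - x.size)])
    wp = pywt.WaveletPacket(data=padded, wavelet="haar", mode="periodization",
                            maxlevel=level)
    return np.stack([node.data for node in wp.get_level(level, order="freq")])


def wavelet_oracle(x, fs: float, bands: dict[str, tuple[float, float]],
                   level: int = 7) -> list[float]:
    """W1..W15 verbatim: pooled node coefficients per band by midpoint rule."""
    nodes = pywt_packet_nodes(x, level)
    width = fs / 2 / 2**level
    out = []
    for lo, hi in bands.values():
        coefs = []
        for k in range(2**level):
            mid = (k + 0.5) * width
            if lo <= mid < hi:
                coefs.extend(nodes[k].tolist())
        N = len(coefs)
        energy = sum(c * c for c in coefs)
        mu = sum(coefs) / N
        variance = sum((c - mu) ** 2 for c in coefs) / (N - 1)
        entropy = sum(c * c * math.log(c * c) for c in coefs if c != 0)
        out.extend([energy, variance, entropy])
    return out


# ------------------------------------------------------------ Poincaré domain
def poincare_oracle(x, m: int) -> tuple[float, float, float, float]:
    """SD1/SD2/product/ratio by hand from the lagged cloud."""
    x = [float(v) for v in x]
    xi = x[: len(x) - m]
    xl = x[m:]
    xa = [(b - a) / math.sqrt(2) for a, b in zip(xi, xl)]
    xb = [(b + a) / math.sqrt(2) for a, b in zip(xi, xl)]
    sd1 = statistics.stdev(xa)
    sd2 = statistics.stdev(xb)
    ratio = sd1 / sd2 if sd2 > 0 else float("nan")
    return sd1, sd2, sd1 * sd2, ratio


# ------------------------------------------------------- band power / p-value
def periodogram_band_power(trials_data: np.ndarray, channel: int,
                           band: tuple[float, float], fs: float) -> float:
    """Mean periodogram power of one channel in a band, averaged over trials."""
    f, pxx = sp_signal.periodogram(trials_data[:, channel - 1, :], fs=fs, axis=-1)
    mask = (f >= band[0]) & (f < band[1])
    return float(pxx[:, mask].mean())


def permutation_pvalue(values: np.ndarray, labels: np.ndarray,
                       n_perm: int = 10_000, seed: int = 0) -> float:
    """Permutation p-value of the group-difference statistic of one column.

    Uses |t| for two groups and the ANOVA F statistic otherwise; the
    observed labeling is included in the null set (+1 correction).
    """
    from scipy import stats

    rng = np.random.default_rng(seed)
    classes = np.unique(labels)

    def stat(lab):
        groups = [values[lab == c] for c in classes]
        if classes.size == 2:
            return abs(stats.ttest_ind(groups[0], groups[1], equal_var=True).statistic)
        return stats.f_oneway(*groups).statistic

    obs = stat(labels)
    hits = 0
    for _ in range(n_perm):
        if stat(rng.permutation(labels)) >= obs:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def nearest_centroid_margin(X: np.ndarray, y: np.ndarray) -> float:
    """Fraction of samples nearer their own class centroid than any other."""
    classes = np.unique(y)
    cents = np.stack([X[y == c].mean(axis=0) for c in classes])
    d = ((X[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
    return float(np.mean(classes[d.argmin(axis=1)] == y))
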