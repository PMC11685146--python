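"""FFT sub-band feature set: energy, variance and entropy per EEG band.

The one-sided DFT of a channel-trial segment is partitioned into the five
canonical EEG bands by half-open frequency intervals ``[f_lo, f_hi)``:
delta 0.5-4, theta 4-8, alpha 8-13, beta 13-30, gamma 30-100 Hz (the DC bin
sits below the 0.5 Hz acquisition cutoff and is excluded).  Per band, with
``y(k)`` the retained complex coefficients and ``M`` their count:

* energy   = sum_k |y(k)|^2
* variance = 1/(M-1) * sum_k (|y(k)| - mean|y|)^2
* entropy  = 1/log(M) * sum_k P(k) log P(k),  P(k) = |y(k)|^2 / energy

The entropy is stored with this (non-positive) sign and natural log; its
magnitude is at most 1 and reaches 1 for a uniform in-band power
distribution.  A zero-power band has entropy 0 by convention; a band with
fewer than two bins has variance NaN with a logged warning.

Feature codes F1..F15 run band-major: F1-F3 delta (energy, variance,
entropy), ..., F13-F15 gamma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical EEG band edges in Hz, in fixed feature order.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 100.0),
}

SPECTRAL_FEATURE_CODES: tuple[str, ...] = tuple(f"F{i}" for i in range(1, 16))

__all__ = [
    "DEFAULT_BANDS",
    "SPECTRAL_FEATURE_CODES",
    "BandSpectrum",
    "band_decompose",
    "spectral_features",
    "spectral_feature_table",
]


@dataclass
class BandSpectrum:
    """In-band one-sided spectrum of one channel-trial segment."""

    band: str
    f_lo: float
    f_hi: float
    freqs: np.ndarray
    y: np.ndarray  # complex coefficients y(k), k = 1..M

    @property
    def M(self) -> int:
        """Number of retained frequency bins."""
        return self.y.size

    @property
    def energy(self) -> float:
        return float(np.sum(np.abs(self.y) ** 2))

    @property
    def P(self) -> np.ndarray:
        """Normalized in-band power distribution; sums to 1 when energy > 0."""
        e = self.energy
        if e == 0:
            return np.zeros(self.M)
        return np.abs(self.y) ** 2 / e


def band_decompose(
    x: np.ndarray,
    fs: float,
    bands: dict[str, tuple[float, float]] | None = None,
) -> list[BandSpectrum]:
    """One-sided FFT of ``x`` split into the given bands.

    Raises ``ValueError`` naming any band that captures no bins at the
    segment's frequency resolution, and requires ``fs`` above twice the
    highest band edge.
    """
    bands = DEFAULT_BANDS if bands is None else bands
    x = np.asarray(x, dtype=np.float64)
    top = max(hi for _, hi in bands.values())
    if fs < 2 * top:
        raise ValueError(f"fs={fs} must be at least twice the top band edge {top} Hz")
    y = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, 1.0 / fs)
    out = []
    for name, (lo, hi) in bands.items():
        mask = (freqs >= lo) & (freqs < hi)
        if not mask.any():
            df = freqs[1] - freqs[0] if freqs.size > 1 else float("nan")
            raise ValueError(
                f"band {name!r} [{lo}, {hi}) Hz captures no bins at resolution {df:.6g} Hz"
            )
        out.append(BandSpectrum(name, lo, hi, freqs[mask], y[mask]))
    return out


def _band_stats(power: np.ndarray, mag: np.ndarray) -> tuple[float, float, float]:
    """(energy, variance, entropy) from in-band |y|^2 and |y| values."""
    M = power.size
    energy = float(power.sum())
    if M < 2:
        variance = float("nan")
        logger.warning("band with %d bin(s): variance undefined, emitting NaN", M)
    else:
        variance = float(np.var(mag, ddof=1))
    if energy == 0 or M < 2:
        entropy = 0.0
    else:
        p = power / energy
        nz = p > 0
        entropy = float(np.sum(p[nz] * np.log(p[nz])) / np.log(M))
    return energy, variance, entropy


def spectral_features(spectra: list[BandSpectrum]) -> np.ndarray:
    """F1..F15 from the five band spectra (delta..gamma order)."""
    if len(spectra) != 5:
        raise ValueError(f"expected 5 band spectra, got {len(spectra)}")
    vals = []
    for bs in spectra:
        mag = np.abs(bs.y)
        vals.extend(_band_stats(mag**2, mag))
    return np.asarray(vals)


def spectral_feature_table(
    X: np.ndarray,
    fs: float,
    bands: dict[str, tuple[float, float]] | None = None,
) -> np.ndarray:
    """Vectorized F1..F15 for every row of ``X``; returns ``(R, 15)``.

    Identical to :func:`spectral_features` applied row-wise.
    """
    bands = DEFAULT_BANDS if bands is None else bands
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    R, n = X.shape
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    Y = np.fft.rfft(X, axis=1)
    out = np.empty((R, 3 * len(bands)))
    for b, (name, (lo, hi)) in enumerate(bands.items()):
        mask = (freqs >= lo) & (freqs < hi)
        M = int(mask.sum())
        if M == 0:
            df = freqs[1] - freqs[0] if freqs.size > 1 else float("nan")
            raise ValueError(
                f"band {name!r} [{lo}, {hi}) Hz captures no bins at resolution {df:.6g} Hz"
            )
        mag = np.abs(Y[:, mask])
        power = mag**2
        energy = power.sum(axis=1)
        if M < 2:
            variance = np.full(R, np.nan)
            logger.warning("band %r has %d bin: variance undefined, emitting NaN", name, M)
        else:
            variance = mag.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = power / energy[:, None]
            plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
            entropy = plogp.sum(axis=1) / np.log(M) if M >= 2 else np.zeros(R)
        entropy = np.where(energy == 0, 0.0, entropy)
        out[:, 3 * b] = energy
        out[:, 3 * b + 1] = variance
        out[:, 3 * b + 2] = entropy
    return out
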