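"""Synthetic motor-imagery EEG with controllable ERD/ERS-like effects.

The generator emulates the structural layout of a standard 22-channel
cue-based MI recording: 250 Hz sampling, 3-s segments, 288 trials per
subject balanced over 4 classes.  Each channel-trial is an independent
realization of 1/f (pink) noise band-limited to the acquisition passband
0.5-100 Hz with the 50 Hz mains bin zeroed, synthesized directly in the
frequency domain.  Class-discriminative structure is injected per
:class:`EffectSpec` by scaling the spectral coefficients of the stated band
on the stated channels by ``sqrt(power_ratio)``, so the in-band power of
affected trials is multiplied by exactly ``power_ratio`` in expectation:
ratios below 1 emulate event-related desynchronization (ERD), above 1
synchronization (ERS).  Per-subject variability enters as a log-normal
jitter of the ratio.

Everything is driven by a single integer seed; identical seed and
parameters give bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .containers import EpochedTrials

__all__ = ["EffectSpec", "generate_dataset"]


@dataclass(frozen=True)
class EffectSpec:
    """A class-dependent band-power modulation on a channel subset.

    Parameters
    ----------
    class_id
        Class whose trials carry the effect (1..K).
    channels
        1-based channel IDs the effect applies to.
    band
        ``(f_lo, f_hi)`` in Hz, ``0 < f_lo < f_hi <= fs/2``.
    power_ratio
        Multiplicative in-band power factor; ``< 1`` is ERD-like,
        ``> 1`` ERS-like.
    jitter
        Per-subject standard deviation of ``log(power_ratio)``.
    """

    class_id: int
    channels: tuple[int, ...]
    band: tuple[float, float]
    power_ratio: float
    jitter: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(int(c) for c in np.atleast_1d(self.channels)))
        object.__setattr__(self, "band", (float(self.band[0]), float(self.band[1])))
        if self.power_ratio <= 0:
            raise ValueError(f"{self}: power_ratio must be > 0")
        if not (0 < self.band[0] < self.band[1]):
            raise ValueError(f"{self}: band must satisfy 0 < f_lo < f_hi")
        if self.jitter < 0:
            raise ValueError(f"{self}: jitter must be >= 0")

    def validate_against(self, fs: float, n_classes: int, n_channels: int) -> None:
        if not (1 <= self.class_id <= n_classes):
            raise ValueError(f"{self}: class_id outside 1..{n_classes}")
        if self.band[1] > fs / 2:
            raise ValueError(f"{self}: band upper edge exceeds Nyquist {fs / 2} Hz")
        for c in self.channels:
            if not (1 <= c <= n_channels):
                raise ValueError(f"{self}: channel {c} outside 1..{n_channels}")


def _amplitude_envelope(
    freqs: np.ndarray,
    passband: tuple[float, float],
    notch: float | None,
    spectral_exponent: float,
) -> np.ndarray:
    """Per-bin amplitude of the background: f^(-gamma/2) inside the passband."""
    env = np.zeros_like(freqs)
    inside = (freqs >= passband[0]) & (freqs <= passband[1])
    env[inside] = freqs[inside] ** (-spectral_exponent / 2.0)
    if notch is not None and freqs.size > 1:
        df = freqs[1] - freqs[0]
        env[np.abs(freqs - notch) < df / 2] = 0.0
    return env


def generate_dataset(
    n_subjects: int = 9,
    trials_per_subject: int = 288,
    effects: Iterable[EffectSpec] = (),
    seed: int = 0,
    *,
    n_classes: int = 4,
    n_channels: int = 22,
    fs: float = 250.0,
    n_samples: int = 750,
    passband: tuple[float, float] = (0.5, 100.0),
    notch: float | None = 50.0,
    spectral_exponent: float = 1.0,
    rms: float = 10.0,
) -> EpochedTrials:
    """Generate a balanced epoched MI-EEG dataset.

    Labels are an exactly balanced permutation per subject
    (``trials_per_subject / n_classes`` trials per class).  The background
    is pink noise shaped to the acquisition passband; ``rms`` sets the
    typical per-channel standard deviation in microvolt-like units.

    Raises ``ValueError`` (naming the offending :class:`EffectSpec`) for an
    invalid class or a band outside Nyquist, and for an unbalanced design.
    """
    effects = list(effects)
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if trials_per_subject % n_classes != 0:
        raise ValueError(
            f"trials_per_subject={trials_per_subject} not divisible by n_classes={n_classes}"
        )
    for eff in effects:
        eff.validate_against(fs, n_classes, n_channels)

    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    env = _amplitude_envelope(freqs, passband, notch, spectral_exponent)
    # Expected time-domain variance of irfft of Z with E|Z_k|^2 = env_k^2
    # (one real DC bin, one Nyquist bin when n even, the rest counted twice).
    weights = np.full(freqs.size, 2.0)
    weights[0] = 1.0
    if n_samples % 2 == 0:
        weights[-1] = 1.0
    expected_var = float(np.sum(weights * env**2)) / n_samples**2
    scale = rms / np.sqrt(expected_var) if expected_var > 0 else 1.0

    per_class = trials_per_subject // n_classes
    base_labels = np.repeat(np.arange(1, n_classes + 1), per_class)
    band_bins = {
        eff: np.flatnonzero((freqs >= eff.band[0]) & (freqs < eff.band[1]))
        for eff in effects
    }

    data = np.empty((n_subjects * trials_per_subject, n_channels, n_samples))
    labels = np.empty(n_subjects * trials_per_subject, dtype=np.int64)
    subjects = np.empty_like(labels)
    for s in range(n_subjects):
        lab = rng.permutation(base_labels)
        jitters = [rng.normal(0.0, eff.jitter) if eff.jitter else 0.0 for eff in effects]
        z = env * (
            rng.standard_normal((trials_per_subject, n_channels, freqs.size))
            + 1j * rng.standard_normal((trials_per_subject, n_channels, freqs.size))
        ) / np.sqrt(2.0)
        for eff, dj in zip(effects, jitters):
            rows = np.flatnonzero(lab == eff.class_id)
            cols = np.asarray(eff.channels) - 1
            amp = np.sqrt(np.exp(np.log(eff.power_ratio) + dj))
            z[np.ix_(rows, cols, band_bins[eff])] *= amp
        sl = slice(s * trials_per_subject, (s + 1) * trials_per_subject)
        data[sl] = np.fft.irfft(z, n=n_samples, axis=-1) * scale
        labels[sl] = lab
        subjects[sl] = s + 1
    return EpochedTrials(data=data, labels=labels, subjects=subjects, fs=fs)
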