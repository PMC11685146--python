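"""Wavelet-packet sub-band feature set (Haar, 7 levels): W1..W15.

A full wavelet-packet tree is taken to depth 7 with the Haar filters and
periodic (periodization) boundary handling, after zero-padding the segment
to the next power of two (750 samples -> 1024).  The 2^7 = 128 terminal
nodes are reordered from the tree's natural order into physical-frequency
(sequency / Gray-code) order, so node ``k`` covers
``[k, k+1) * fs/2 / 128`` Hz — 0.9765625 Hz wide at fs = 250.

A terminal node is assigned to the EEG band whose half-open interval
contains the node's midpoint frequency; the assignment table is logged.
Per band, pooling the coefficients ``c`` of its nodes (N coefficients,
mean mu):

* energy   = sum c^2
* variance = 1/(N-1) * sum (c - mu)^2
* entropy  = sum c^2 * log(c^2),  with 0*log(0) := 0

The entropy is kept exactly in this unnormalized, sign-unflipped form
(see docs/methods.md for the discussion of this convention).  Codes
W1..W15 mirror F1..F15: band-major delta..gamma, (energy, variance,
entropy) within each band.

The transform is a vectorized in-package implementation of the Haar
packet butterflies; it is coefficient-exact against PyWavelets'
``WaveletPacket(..., wavelet='haar', mode='periodization')`` with
``order='freq'``, which the test suite uses as the independent oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .spectral import DEFAULT_BANDS

logger = logging.getLogger(__name__)

WAVELET_FEATURE_CODES: tuple[str, ...] = tuple(f"W{i}" for i in range(1, 16))

_SQRT2 = np.sqrt(2.0)

__all__ = [
    "WAVELET_FEATURE_CODES",
    "WaveletDecomposition",
    "wpt_decompose",
    "wavelet_band_features",
    "wavelet_feature_table",
    "node_band_table",
]


@dataclass
class WaveletDecomposition:
    """Terminal wavelet-packet coefficients of one channel-trial segment.

    ``nodes`` has shape ``(2**level, coeffs_per_node)`` in frequency
    (sequency) order; ``node_edges`` gives each node's ``[f_lo, f_hi)``
    interval in Hz.
    """

    nodes: np.ndarray
    fs: float
    level: int
    node_edges: np.ndarray  # (2**level, 2)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def node_width_hz(self) -> float:
        return self.fs / 2 / self.n_nodes

    def node_energies(self) -> np.ndarray:
        return (self.nodes**2).sum(axis=1)


def _haar_packet_nodes(X: np.ndarray, level: int) -> np.ndarray:
    """Full Haar packet tree of each row; returns (R, 2**level, m) in
    natural tree order.  Rows must have power-of-two length >= 2**level."""
    R, n = X.shape
    nodes = X.reshape(R, 1, n)
    for _ in range(level):
        a = (nodes[..., ::2] + nodes[..., 1::2]) / _SQRT2
        d = (nodes[..., ::2] - nodes[..., 1::2]) / _SQRT2
        nodes = np.stack([a, d], axis=2).reshape(R, nodes.shape[1] * 2, n >> 1)
        n >>= 1
    return nodes


def _gray_permutation(level: int) -> np.ndarray:
    k = np.arange(2**level)
    return k ^ (k >> 1)


def _padded_length(n: int, level: int) -> int:
    m = max(2**level, 1)
    while m < n:
        m <<= 1
    return m


def _node_edges(fs: float, level: int) -> np.ndarray:
    width = fs / 2 / 2**level
    k = np.arange(2**level)
    return np.stack([k * width, (k + 1) * width], axis=1)


def wpt_table(X: np.ndarray, level: int = 7) -> np.ndarray:
    """Frequency-ordered terminal nodes for every row; (R, 2**level, m)."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    R, n = X.shape
    if n < 2**level:
        raise ValueError(f"series length must be >= 2**{level} = {2**level}, got {n}")
    npad = _padded_length(n, level)
    if npad != n:
        X = np.concatenate([X, np.zeros((R, npad - n))], axis=1)
    nodes = _haar_packet_nodes(X, level)
    return nodes[:, _gray_permutation(level), :]


def wpt_decompose(x: np.ndarray, fs: float, level: int = 7) -> WaveletDecomposition:
    """Depth-``level`` Haar wavelet-packet decomposition of one series.

    Zero-pads to a dyadic length (pad-region coefficients retained, so the
    Parseval identity holds exactly on the padded signal) and returns the
    terminal nodes in physical-frequency order.
    """
    nodes = wpt_table(np.asarray(x, dtype=np.float64)[None, :], level)[0]
    return WaveletDecomposition(
        nodes=nodes, fs=fs, level=level, node_edges=_node_edges(fs, level)
    )


def node_band_table(
    fs: float,
    level: int = 7,
    bands: dict[str, tuple[float, float]] | None = None,
) -> dict[str, np.ndarray]:
    """Band -> terminal-node-index assignment by the midpoint rule.

    A node belongs to band ``b`` iff its interval midpoint lies in
    ``[f_lo, f_hi)``.  Raises ``ValueError`` for a band narrower than one
    node.  The table is logged at INFO level.
    """
    bands = DEFAULT_BANDS if bands is None else bands
    edges = _node_edges(fs, level)
    mid = edges.mean(axis=1)
    width = fs / 2 / 2**level
    table = {}
    for name, (lo, hi) in bands.items():
        if hi - lo < width:
            raise ValueError(
                f"band {name!r} [{lo}, {hi}) Hz is narrower than the "
                f"{width:.4f} Hz terminal-node resolution"
            )
        idx = np.flatnonzero((mid >= lo) & (mid < hi))
        if idx.size == 0:
            raise ValueError(
                f"band {name!r} [{lo}, {hi}) Hz contains no node midpoint at "
                f"{width:.4f} Hz resolution"
            )
        table[name] = idx
        logger.info(
            "band %-6s [%g, %g) Hz <- nodes %d..%d (%d nodes of width %.7g Hz)",
            name, lo, hi, idx[0], idx[-1], idx.size, width,
        )
    return table


def _pooled_stats(coefs: np.ndarray) -> tuple[float, float, float]:
    sq = coefs**2
    energy = float(sq.sum())
    variance = float(np.var(coefs, ddof=1)) if coefs.size > 1 else float("nan")
    nz = sq > 0
    entropy = float(np.sum(sq[nz] * np.log(sq[nz])))
    return energy, variance, entropy


def wavelet_band_features(
    dec: WaveletDecomposition,
    bands: dict[str, tuple[float, float]] | None = None,
) -> np.ndarray:
    """W1..W15 from a decomposition: per band (energy, variance, entropy)."""
    table = node_band_table(dec.fs, dec.level, bands)
    vals = []
    for idx in table.values():
        vals.extend(_pooled_stats(dec.nodes[idx].ravel()))
    return np.asarray(vals)


def wavelet_feature_table(
    X: np.ndarray,
    fs: float,
    bands: dict[str, tuple[float, float]] | None = None,
    level: int = 7,
) -> np.ndarray:
    """Vectorized W1..W15 for every row of ``X``; returns ``(R, 15)``."""
    nodes = wpt_table(X, level)
    table = node_band_table(fs, level, bands)
    R = nodes.shape[0]
    out = np.empty((R, 3 * len(table)))
    for b, idx in enumerate(table.values()):
        coefs = nodes[:, idx, :].reshape(R, -1)
        sq = coefs**2
        out[:, 3 * b] = sq.sum(axis=1)
        out[:, 3 * b + 1] = coefs.var(axis=1, ddof=1)
        logsq = np.where(sq > 0, np.log(np.where(sq > 0, sq, 1.0)), 0.0)
        out[:, 3 * b + 2] = (sq * logsq).sum(axis=1)
    return out
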