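"""Epoched multichannel EEG trials: the pipeline's single input container.

An :class:`EpochedTrials` holds a real tensor of shape
``(n_trials, n_channels, n_samples)`` (microvolt-scale arbitrary units)
together with one integer class label and one integer subject ID per trial
and the sampling rate in Hz.  The reference layout mirrors a standard
cue-based motor-imagery recording: 22 channels at 250 Hz, 3-s segments
(750 samples), 288 trials per subject balanced over 4 imagery classes.

On disk a dataset is a directory of per-subject delimited numeric files plus
a JSON sidecar carrying labels, subjects and the sampling rate, so fixtures
stay plain-text and diff-able.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["EpochedTrials", "subset_binary", "write_trials", "read_trials"]

_META_FILE = "meta.json"
_REQUIRED_META = ("fs", "labels", "subjects", "n_channels", "n_samples")


@dataclass
class EpochedTrials:
    """Labeled trial tensor with per-trial class labels and subject IDs.

    Parameters
    ----------
    data
        Real array ``(n_trials, n_channels, n_samples)``; must be finite.
    labels
        Integer class per trial, values in ``1..K``.
    subjects
        Integer subject ID per trial.
    fs
        Sampling rate in Hz.
    channel_ids
        1-based channel identifiers; defaults to ``1..n_channels``.
    """

    data: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    fs: float
    channel_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subjects = np.asarray(self.subjects, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (n_trials, n_channels, n_samples); got shape {self.data.shape}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        n = self.data.shape[0]
        if self.labels.shape != (n,):
            raise ValueError(
                f"labels length {self.labels.shape} does not match n_trials={n}"
            )
        if self.subjects.shape != (n,):
            raise ValueError(
                f"subjects length {self.subjects.shape} does not match n_trials={n}"
            )
        if n and self.labels.min() < 1:
            raise ValueError("labels must be positive (1..K)")
        if self.channel_ids is None:
            self.channel_ids = np.arange(1, self.data.shape[1] + 1)
        else:
            self.channel_ids = np.asarray(self.channel_ids, dtype=np.int64)
            if self.channel_ids.shape != (self.data.shape[1],):
                raise ValueError("channel_ids length must equal n_channels")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def classes(self) -> np.ndarray:
        """Sorted distinct class labels present."""
        return np.unique(self.labels)

    def subject_ids(self) -> np.ndarray:
        return np.unique(self.subjects)

    def select_trials(self, index: np.ndarray) -> "EpochedTrials":
        """Return a copy restricted to the given trial index (order kept)."""
        return EpochedTrials(
            data=self.data[index],
            labels=self.labels[index],
            subjects=self.subjects[index],
            fs=self.fs,
            channel_ids=self.channel_ids.copy(),
        )


def subset_binary(trials: EpochedTrials, class_a: int, class_b: int) -> EpochedTrials:
    """Restrict to two classes and remap labels to {1, 2}.

    ``class_a`` becomes 1 and ``class_b`` becomes 2; trial order is preserved.
    Raises ``ValueError`` naming any class that is absent.
    """
    if class_a == class_b:
        raise ValueError("class_a and class_b must differ")
    present = set(trials.classes().tolist())
    for c in (class_a, class_b):
        if c not in present:
            raise ValueError(f"class {c} is not present in the dataset")
    keep = np.flatnonzero(np.isin(trials.labels, [class_a, class_b]))
    out = trials.select_trials(keep)
    remapped = np.where(out.labels == class_a, 1, 2)
    out.labels = remapped.astype(np.int64)
    return out


def write_trials(trials: EpochedTrials, path: str | Path) -> Path:
    """Write a dataset as per-subject CSV files plus a JSON sidecar.

    Each subject file stacks that subject's trials in dataset order, one
    channel per row (``n_trials_s * n_channels`` rows, ``n_samples``
    columns).  Floats use 17 significant digits so the round-trip is exact
    at binary double precision.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "fs": float(trials.fs),
        "labels": trials.labels.tolist(),
        "subjects": trials.subjects.tolist(),
        "channel_ids": trials.channel_ids.tolist(),
        "n_channels": int(trials.n_channels),
        "n_samples": int(trials.n_samples),
    }
    (path / _META_FILE).write_text(json.dumps(meta))
    for s in trials.subject_ids():
        block = trials.data[trials.subjects == s]
        flat = block.reshape(-1, trials.n_samples)
        np.savetxt(path / f"subject_{int(s)}.csv", flat, fmt="%.17g", delimiter=",")
    return path


def read_trials(path: str | Path) -> EpochedTrials:
    """Read a dataset written by :func:`write_trials`.

    Raises ``ValueError`` listing any missing metadata field or any
    dimension mismatch between the sidecar and the numeric files.
    """
    path = Path(path)
    meta_path = path / _META_FILE
    if not meta_path.exists():
        raise ValueError(f"missing {_META_FILE} in {path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed {_META_FILE}: {exc}") from exc
    missing = [k for k in _REQUIRED_META if k not in meta]
    if missing:
        raise ValueError(f"{_META_FILE} is missing required fields: {missing}")
    labels = np.asarray(meta["labels"], dtype=np.int64)
    subjects = np.asarray(meta["subjects"], dtype=np.int64)
    if labels.shape != subjects.shape:
        raise ValueError("labels and subjects lengths differ in metadata")
    n_channels = int(meta["n_channels"])
    n_samples = int(meta["n_samples"])
    n_trials = labels.size
    data = np.empty((n_trials, n_channels, n_samples), dtype=np.float64)
    for s in np.unique(subjects):
        fname = path / f"subject_{int(s)}.csv"
        if not fname.exists():
            raise ValueError(f"missing data file {fname.name} for subject {int(s)}")
        flat = np.loadtxt(fname, delimiter=",", ndmin=2)
        idx = np.flatnonzero(subjects == s)
        expected = (idx.size * n_channels, n_samples)
        if flat.shape != expected:
            raise ValueError(
                f"{fname.name}: expected shape {expected}, found {flat.shape}"
            )
        data[idx] = flat.reshape(idx.size, n_channels, n_samples)
    if n_trials != len(meta["labels"]):
        raise ValueError("labels length does not match n_trials")
    return EpochedTrials(
        data=data,
        labels=labels,
        subjects=subjects,
        fs=float(meta["fs"]),
        channel_ids=np.asarray(meta.get("channel_ids", np.arange(1, n_channels + 1))),
    )
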