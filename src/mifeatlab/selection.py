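"""Pooled feature matrix, significance filtering and distribution maps.

The pooled :class:`FeatureMatrix` stacks all trials (rows) against the
per-channel feature battery (columns), ordered domain-major, then feature
type, then channel: ``T1_ch1 .. T1_ch22, T2_ch1, ...``.  Over a 22-channel
montage the four domains give 24, 15, 15 and 8 feature types per channel,
hence 528 + 330 + 330 + 176 = 1,364 columns.

Feature screening is mass-univariate: a two-sided equal-variance
independent t-test per column for two classes, a one-way ANOVA F-test for
more, and a strict ``p < alpha`` mask at alpha = 0.05 by default.  No
multiple-testing correction is applied — the screen intentionally
thresholds raw p-values (the caveat is documented in docs/methods.md), and
it runs on the full pooled matrix, not within cross-validation folds.

A :class:`DistributionMap` is the per-domain boolean channel x feature-type
grid of surviving features with row/column totals, renderable as a
check-mark text table or CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import EpochedTrials
from .features.poincare import POINCARE_FEATURE_CODES, poincare_feature_table
from .features.spectral import SPECTRAL_FEATURE_CODES, spectral_feature_table
from .features.timedomain import TIME_FEATURE_CODES, time_feature_table
from .features.wavelet import WAVELET_FEATURE_CODES, wavelet_feature_table

logger = logging.getLogger(__name__)

#: Feature types per domain code.
DOMAIN_CODES: dict[str, tuple[str, ...]] = {
    "T": TIME_FEATURE_CODES,
    "F": SPECTRAL_FEATURE_CODES,
    "W": WAVELET_FEATURE_CODES,
    "P": POINCARE_FEATURE_CODES,
}

ALL_DOMAINS: tuple[str, ...] = ("T", "F", "W", "P")

__all__ = [
    "DOMAIN_CODES",
    "ALL_DOMAINS",
    "FeatureDescriptor",
    "FeatureMatrix",
    "SelectionResult",
    "DistributionMap",
    "build_feature_matrix",
    "significance_filter",
    "distribution_map",
]


@dataclass(frozen=True)
class FeatureDescriptor:
    """Identity of one feature column: domain, per-domain type, channel."""

    domain: str
    type_index: int  # 1-based within the domain
    channel: int  # 1-based channel id

    @property
    def code(self) -> str:
        return f"{self.domain}{self.type_index}"

    @property
    def name(self) -> str:
        return f"{self.code}_ch{self.channel}"


@dataclass
class FeatureMatrix:
    """Pooled samples x features table with per-column descriptors."""

    values: np.ndarray
    descriptors: list[FeatureDescriptor]
    labels: np.ndarray
    subjects: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.descriptors):
            raise ValueError("descriptor count must match number of columns")
        if self.values.shape[0] != self.labels.size:
            raise ValueError("labels length must match number of rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def column_names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def domains(self) -> tuple[str, ...]:
        seen: list[str] = []
        for d in self.descriptors:
            if d.domain not in seen:
                seen.append(d.domain)
        return tuple(seen)

    def select_columns(self, mask: np.ndarray) -> "FeatureMatrix":
        idx = np.flatnonzero(mask)
        return FeatureMatrix(
            values=self.values[:, idx],
            descriptors=[self.descriptors[i] for i in idx],
            labels=self.labels,
            subjects=self.subjects,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names)
        df.insert(0, "subject", self.subjects)
        df.insert(0, "label", self.labels)
        return df


_DOMAIN_TABLES = {
    "T": lambda X, trials, bands: time_feature_table(X),
    "F": lambda X, trials, bands: spectral_feature_table(X, trials.fs, bands),
    "W": lambda X, trials, bands: wavelet_feature_table(X, trials.fs, bands),
    "P": lambda X, trials, bands: poincare_feature_table(X),
}


def build_feature_matrix(
    trials: EpochedTrials,
    domains: tuple[str, ...] = ALL_DOMAINS,
    *,
    bands: dict[str, tuple[float, float]] | None = None,
    chunk_trials: int = 256,
    max_nan_fraction: float = 0.5,
) -> FeatureMatrix:
    """Extract the selected feature domains for every trial and channel.

    Columns are ordered domain-major (in the order given), then feature
    type, then channel; rows follow trial order pooled over subjects.
    Extraction is chunked over trials to bound memory.  A column whose NaN
    fraction exceeds ``max_nan_fraction`` (degenerate inputs) raises
    ``ValueError`` naming the feature.
    """
    if not domains:
        raise ValueError("domains must be non-empty")
    bad = [d for d in domains if d not in DOMAIN_CODES]
    if bad:
        raise ValueError(f"unknown domain codes: {bad}; valid codes are {list(DOMAIN_CODES)}")

    nt, nc, ns = trials.data.shape
    descriptors = [
        FeatureDescriptor(d, t + 1, int(ch))
        for d in domains
        for t in range(len(DOMAIN_CODES[d]))
        for ch in trials.channel_ids
    ]
    values = np.empty((nt, len(descriptors)))
    for start in range(0, nt, chunk_trials):
        stop = min(start + chunk_trials, nt)
        X = trials.data[start:stop].reshape(-1, ns)  # (trials*channels, samples)
        col = 0
        for d in domains:
            table = _DOMAIN_TABLES[d](X, trials, bands)  # (rows, n_types)
            n_types = table.shape[1]
            block = table.reshape(stop - start, nc, n_types).transpose(0, 2, 1)
            values[start:stop, col : col + n_types * nc] = block.reshape(stop - start, -1)
            col += n_types * nc
    nan_frac = np.isnan(values).mean(axis=0)
    worst = int(np.argmax(nan_frac))
    if nan_frac[worst] > max_nan_fraction:
        raise ValueError(
            f"feature {descriptors[worst].name} is NaN in "
            f"{nan_frac[worst]:.0%} of samples (degenerate inputs)"
        )
    return FeatureMatrix(
        values=values,
        descriptors=descriptors,
        labels=trials.labels.copy(),
        subjects=trials.subjects.copy(),
    )


@dataclass
class SelectionResult:
    """Per-feature p-values and the strict ``p < alpha`` mask."""

    p_values: np.ndarray
    mask: np.ndarray
    alpha: float
    method: str  # "t-test" | "ANOVA"

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


def significance_filter(
    fm: FeatureMatrix,
    alpha: float = 0.05,
    *,
    equal_var: bool = True,
) -> SelectionResult:
    """Mass-univariate significance screen of every feature column.

    Two classes: two-sided independent two-sample t-test (Student by
    default; Welch with ``equal_var=False``).  More classes: one-way ANOVA
    F-test.  Zero-variance columns get ``p = 1`` with a logged warning.
    Requires at least two samples in every class.
    """
    classes = np.unique(fm.labels)
    if classes.size < 2:
        raise ValueError("need at least 2 classes for significance testing")
    groups = [fm.values[fm.labels == c] for c in classes]
    for c, g in zip(classes, groups):
        if g.shape[0] < 2:
            raise ValueError(f"class {int(c)} has fewer than 2 samples")
    import warnings as _warnings

    with np.errstate(divide="ignore", invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # constant columns handled below
        if classes.size == 2:
            method = "t-test"
            _, p = stats.ttest_ind(groups[0], groups[1], axis=0, equal_var=equal_var)
        else:
            method = "ANOVA"
            _, p = stats.f_oneway(*groups, axis=0)
    p = np.asarray(p, dtype=np.float64)
    zero_var = np.nanvar(fm.values, axis=0) == 0
    undefined = ~np.isfinite(p)
    if np.any(zero_var | undefined):
        logger.warning(
            "%d zero-variance/undefined column(s): setting p = 1",
            int(np.count_nonzero(zero_var | undefined)),
        )
        p[zero_var | undefined] = 1.0
    return SelectionResult(p_values=p, mask=p < alpha, alpha=alpha, method=method)


@dataclass
class DistributionMap:
    """Boolean feature-type x channel grid of selected features, one domain."""

    domain: str
    grid: np.ndarray  # (n_types, n_channels) bool
    type_codes: tuple[str, ...]
    channel_ids: np.ndarray
    row_totals: np.ndarray = field(init=False)
    column_totals: np.ndarray = field(init=False)
    grand_total: int = field(init=False)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        self.row_totals = self.grid.sum(axis=1)
        self.column_totals = self.grid.sum(axis=0)
        self.grand_total = int(self.grid.sum())

    def render_text(self, mark: str = "✓") -> str:
        """Check-mark table with per-row/column totals, like the printed maps."""
        head = ["F"] + [str(int(c)) for c in self.channel_ids] + ["T"]
        rows = [head]
        for t, code in enumerate(self.type_codes):
            rows.append(
                [code]
                + [mark if self.grid[t, c] else "" for c in range(self.grid.shape[1])]
                + [str(int(self.row_totals[t]))]
            )
        rows.append(
            ["T"] + [str(int(v)) for v in self.column_totals] + [str(self.grand_total)]
        )
        widths = [max(len(r[i]) for r in rows) for i in range(len(head))]
        return "\n".join(
            "  ".join(cell.ljust(w) for cell, w in zip(r, widths)) for r in rows
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.grid.astype(int),
            index=list(self.type_codes),
            columns=[int(c) for c in self.channel_ids],
        )
        df["T"] = self.row_totals
        totals = df.sum(axis=0)
        totals.name = "T"
        return pd.concat([df, totals.to_frame().T])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="F")

    @classmethod
    def from_csv(cls, path: str | Path, domain: str | None = None) -> "DistributionMap":
        df = pd.read_csv(path, index_col=0)
        body = df.iloc[:-1].drop(columns=["T"])
        codes = tuple(body.index.astype(str))
        if domain is None:
            domain = codes[0][0]
        return cls(
            domain=domain,
            grid=body.to_numpy(dtype=bool),
            type_codes=codes,
            channel_ids=body.columns.astype(int).to_numpy(),
        )


def distribution_map(
    sel: SelectionResult, fm: FeatureMatrix, domain: str
) -> DistributionMap:
    """Channel x feature-type map of the selected features of one domain."""
    if domain not in fm.domains():
        raise ValueError(f"domain {domain!r} not present in the feature matrix")
    channels = np.unique([d.channel for d in fm.descriptors])
    codes = DOMAIN_CODES[domain]
    grid = np.zeros((len(codes), channels.size), dtype=bool)
    chan_pos = {int(c): i for i, c in enumerate(channels)}
    for j, desc in enumerate(fm.descriptors):
        if desc.domain == domain and sel.mask[j]:
            grid[desc.type_index - 1, chan_pos[desc.channel]] = True
    return DistributionMap(
        domain=domain, grid=grid, type_codes=codes, channel_ids=channels
    )
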