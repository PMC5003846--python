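"""Core in-memory containers for targeted-panel counts and genome-wide expression.

Both containers pair a genes x samples matrix with per-sample annotations
(condition and cell line), which downstream operations key on.  Validation is
strict and happens at construction time: malformed inputs fail loudly rather
than propagating silently through the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical probe classes on a hybridization count panel.
PROBE_CLASSES = ("endogenous", "negative", "positive", "housekeeping")

#: Required columns in every sample-annotation table.
SAMPLE_COLUMNS = ("condition", "cell_line")


class FormatError(ValueError):
    """Raised when an input file or table violates the expected format."""


def _check_samples(samples: pd.DataFrame, sample_ids: pd.Index) -> pd.DataFrame:
    if samples.index.has_duplicates:
        dups = samples.index[samples.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample ids in annotations: {dups}")
    missing = [s for s in sample_ids if s not in samples.index]
    if missing:
        raise FormatError(f"samples missing from annotations: {missing}")
    for col in SAMPLE_COLUMNS:
        if col not in samples.columns:
            raise FormatError(f"sample annotations lack required column '{col}'")
    samples = samples.loc[sample_ids, list(SAMPLE_COLUMNS)].copy()
    if samples["condition"].isna().any():
        bad = samples.index[samples["condition"].isna()].tolist()
        raise FormatError(f"samples without a condition label: {bad}")
    samples["condition"] = samples["condition"].astype(str)
    samples["cell_line"] = samples["cell_line"].fillna("unspecified").astype(str)
    return samples


@dataclass
class PanelRun:
    """Raw targeted-panel counts with probe classes and sample annotations.

    Parameters
    ----------
    counts
        Non-negative integer counts, genes x samples.
    probe_class
        Per-gene probe class, one of :data:`PROBE_CLASSES`; indexed like
        ``counts``.
    samples
        Per-sample annotations indexed by sample id with columns
        ``condition`` and ``cell_line``.
    """

    counts: pd.DataFrame
    probe_class: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene names: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        values = counts.to_numpy()
        if values.size == 0:
            raise FormatError("empty count matrix")
        if not np.isfinite(values).all():
            raise FormatError("counts contain non-finite values")
        if (values < 0).any():
            raise FormatError("counts must be non-negative")
        if not np.array_equal(values, np.floor(values)):
            raise FormatError("non-integer count in matrix")
        self.counts = counts.astype(np.int64)

        pc = self.probe_class.reindex(counts.index)
        if pc.isna().any():
            bad = pc.index[pc.isna()].tolist()
            raise FormatError(f"genes without a probe class: {bad}")
        unknown = sorted(set(pc.unique()) - set(PROBE_CLASSES))
        if unknown:
            raise FormatError(f"unknown probe class(es): {unknown}")
        if (pc == "negative").sum() < 1:
            raise FormatError("panel has no negative-control probe")
        if (pc == "endogenous").sum() < 1:
            raise FormatError("panel has no endogenous probe")
        self.probe_class = pc.astype(str)

        self.samples = _check_samples(self.samples, counts.columns)

    # -- convenience accessors ------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def genes_of_class(self, probe_class: str) -> list[str]:
        return list(self.probe_class.index[self.probe_class == probe_class])

    @property
    def measured_genes(self) -> list[str]:
        """Endogenous plus housekeeping probes (the biologically meaningful rows)."""
        keep = self.probe_class.isin(["endogenous", "housekeeping"])
        return list(self.probe_class.index[keep])

    @property
    def negative_counts(self) -> pd.DataFrame:
        return self.counts.loc[self.genes_of_class("negative")]


@dataclass
class ExpressionMatrix:
    """Processed genome-wide expression on log2 scale, genes x samples.

    Missing entries are NaN and are never imputed; each operation states how
    it handles them.
    """

    values: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = self.values
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene names: {dups}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if values.shape[1] < 2:
            raise FormatError("expression matrix needs at least 2 samples")
        arr = values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise FormatError("expression values must be finite or missing")
        self.values = values.astype(float)
        if self.samples is None:
            self.samples = pd.DataFrame(
                {"condition": "unspecified", "cell_line": "unspecified"},
                index=values.columns,
            )
        self.samples = _check_samples(self.samples, values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)
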