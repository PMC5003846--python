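"""Quality control: effector-cell contamination screen and platform concordance.

Sorted tumor-cell samples from a co-culture can carry over T cells.  The
contamination screen compares normalized counts of T-cell marker genes
(default CD3D/CD3E/CD3G/CD8A/CD8B) against a background threshold derived
from the negative-control probes: B = pooled mean + k·SD (default k = 2) of
the negative-control counts after each sample's normalization scale has been
applied to them, so markers and threshold live on the same scale.  A marker
above B flags the sample.

Cross-platform concordance between two fold-change tables (e.g. genome-wide
microarray vs targeted count panel) is summarized by the Pearson correlation
of per-gene log fold-changes and by the OLS slope of platform a on platform
b: a slope below 1 means platform a compresses fold-changes relative to b.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PanelRun
from .diffexpr import FoldChangeTable
from .normalization import NormalizationResult

DEFAULT_MARKERS = ("CD3D", "CD3E", "CD3G", "CD8A", "CD8B")


@dataclass
class ContaminationReport:
    """Per-sample, per-marker contamination verdicts.

    ``table`` is tidy: one row per (sample, marker) with the normalized
    linear count and a verdict ("pass" or "flag"); ``threshold`` is the
    background level B; ``flagged`` maps each flagged sample to its offending
    markers.
    """

    table: pd.DataFrame
    threshold: float
    markers: list[str]
    flagged: dict[str, list[str]] = field(default_factory=dict)

    @property
    def clean(self) -> bool:
        return not self.flagged


def contamination_check(
    norm: NormalizationResult,
    run: PanelRun,
    markers: tuple[str, ...] | list[str] = DEFAULT_MARKERS,
    bg_k: float = 2.0,
) -> ContaminationReport:
    """Screen samples for effector-cell contamination via marker genes.

    Marker counts are the normalized linear values; a marker that was masked
    during normalization (count at or below background) is treated as 0 and
    passes.  The threshold B = mean + ``bg_k``·SD is pooled over every
    negative-control entry after per-sample normalization (each sample's
    negatives multiplied by its scale 2^(−d_j)).
    """
    markers = list(markers)
    absent = [m for m in markers if m not in norm.linear_values.index]
    if absent:
        raise ValueError(f"marker(s) absent from panel: {absent}")

    scale = np.power(2.0, -norm.shift)
    negatives = run.negative_counts.astype(float).mul(scale, axis=1)
    flat = negatives.to_numpy().ravel()
    threshold = float(flat.mean() + bg_k * flat.std(ddof=1)) if flat.size > 1 else float(
        flat.mean()
    )

    counts = norm.linear_values.loc[markers].fillna(0.0)
    rows = []
    flagged: dict[str, list[str]] = {}
    for sample in counts.columns:
        for marker in markers:
            value = float(counts.loc[marker, sample])
            verdict = "flag" if value > threshold else "pass"
            if verdict == "flag":
                flagged.setdefault(sample, []).append(marker)
            rows.append((sample, marker, value, verdict))
    table = pd.DataFrame(rows, columns=["sample_id", "marker", "count", "verdict"])
    return ContaminationReport(
        table=table, threshold=threshold, markers=markers, flagged=flagged
    )


@dataclass
class ConcordanceReport:
    """Cross-platform fold-change concordance summary.

    ``pearson_r`` and ``compression_slope`` describe the pooled comparison
    (slope of platform a regressed on platform b); ``per_cell_line`` holds
    the same statistics per shared cell line when labels align.
    """

    pearson_r: float
    compression_slope: float
    intercept: float
    n_genes: int
    per_cell_line: pd.DataFrame | None = None


def _concordance(a: pd.Series, b: pd.Series) -> tuple[float, float, float, int]:
    shared = a.index.intersection(b.index)
    x = b.loc[shared].to_numpy(dtype=float)
    y = a.loc[shared].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"need at least 3 shared genes with finite logfc, got {len(x)}")
    fit = stats.linregress(x, y)
    r = stats.pearsonr(x, y).statistic
    return float(r), float(fit.slope), float(fit.intercept), int(len(x))


def compare_platforms(
    fc_a: FoldChangeTable,
    fc_b: FoldChangeTable,
    genes: list[str] | None = None,
) -> ConcordanceReport:
    """Concordance of per-gene log fold-changes between two platforms.

    Compares the cross-line mean logfc (restricted to ``genes`` when given)
    and, where cell-line labels coincide, each shared cell line separately.
    ``compression_slope`` < 1 means platform a understates fold-changes
    relative to platform b.
    """
    a, b = fc_a.mean_logfc, fc_b.mean_logfc
    if genes is not None:
        a, b = a.loc[a.index.intersection(genes)], b.loc[b.index.intersection(genes)]
    r, slope, intercept, n = _concordance(a, b)

    per_line = None
    shared_lines = [c for c in fc_a.cell_lines if c in fc_b.cell_lines]
    if shared_lines:
        rows = []
        for line in shared_lines:
            la, lb = fc_a.logfc[line], fc_b.logfc[line]
            if genes is not None:
                la = la.loc[la.index.intersection(genes)]
                lb = lb.loc[lb.index.intersection(genes)]
            try:
                lr, lslope, lint, ln = _concordance(la, lb)
            except ValueError:
                continue
            rows.append((line, lr, lslope, lint, ln))
        if rows:
            per_line = pd.DataFrame(
                rows,
                columns=["cell_line", "pearson_r", "compression_slope", "intercept", "n_genes"],
            ).set_index("cell_line")
    return ConcordanceReport(
        pearson_r=r,
        compression_slope=slope,
        intercept=intercept,
        n_genes=n,
        per_cell_line=per_line,
    )
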