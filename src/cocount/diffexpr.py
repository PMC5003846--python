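"""Pseudocount-adjusted condition fold-changes and the consensus fold filter.

Per gene and cell line, the log2 fold-change between a treated and an
untreated condition is computed from normalized *linear* counts as

    logfc = log2(mean_treated + k) − log2(mean_untreated + k)

with pseudocount k (default 10 counts).  The pseudocount damps the blow-up
of ratios when a gene is barely expressed in one condition: a gene going
from 0 to 10 counts reads as a 2-fold change, not an infinite one.  Condition
means average linear values over all samples of the condition, with missing
values (counts at or below background, masked during normalization)
contributing as 0 counts — undetected is treated as absent, not dropped.

A gene is called differentially expressed by the consensus filter when its
fold-change clears a threshold F (default 4) *in every cell line, in the
same direction* — the conservative reading of "at least F-fold in all cell
lines".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .normalization import NormalizationResult

DEFAULT_PSEUDOCOUNT = 10.0


@dataclass
class FoldChangeTable:
    """Per-gene, per-cell-line log2 fold-changes (treated vs untreated).

    Attributes
    ----------
    logfc
        genes x cell lines log2 fold-changes.
    mean_logfc
        Per-gene mean across cell lines.
    pseudocount
        The linear-count pseudocount k used.
    group_sizes
        cell line x condition sample counts.
    treated, untreated
        The two condition labels compared.
    """

    logfc: pd.DataFrame
    mean_logfc: pd.Series
    pseudocount: float
    group_sizes: pd.DataFrame
    treated: str
    untreated: str

    @property
    def cell_lines(self) -> list[str]:
        return list(self.logfc.columns)

    def to_frame(self) -> pd.DataFrame:
        out = self.logfc.copy()
        out["mean_logfc"] = self.mean_logfc
        return out


def condition_logfc(
    norm: NormalizationResult | pd.DataFrame,
    samples: pd.DataFrame,
    treated: str,
    untreated: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> FoldChangeTable:
    """Pseudocount log2 fold-changes per cell line from normalized linear counts.

    ``norm`` is a :class:`~cocount.normalization.NormalizationResult` or a
    plain genes x samples matrix of normalized linear counts; ``samples`` maps
    sample ids to ``condition`` and ``cell_line``.  Every cell line having a
    sample in either condition must have at least one sample in both.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    linear = norm.linear_values if isinstance(norm, NormalizationResult) else norm
    samples = samples.loc[linear.columns]
    relevant = samples[samples["condition"].isin([treated, untreated])]
    if relevant.empty:
        raise ValueError(
            f"no samples with condition '{treated}' or '{untreated}'"
        )
    cell_lines = sorted(relevant["cell_line"].unique())

    logfc = {}
    sizes = {}
    for line in cell_lines:
        in_line = relevant[relevant["cell_line"] == line]
        t_ids = in_line.index[in_line["condition"] == treated]
        u_ids = in_line.index[in_line["condition"] == untreated]
        if len(t_ids) == 0 or len(u_ids) == 0:
            empty = treated if len(t_ids) == 0 else untreated
            raise ValueError(
                f"cell line '{line}' has zero samples in condition '{empty}'"
            )
        # undetected (masked) values count as 0 in the condition mean
        mean_t = linear[t_ids].fillna(0.0).mean(axis=1)
        mean_u = linear[u_ids].fillna(0.0).mean(axis=1)
        # difference of logs (not log of ratio) → label swap negates bit-exactly
        logfc[line] = np.log2(mean_t + pseudocount) - np.log2(mean_u + pseudocount)
        sizes[line] = {treated: len(t_ids), untreated: len(u_ids)}

    logfc = pd.DataFrame(logfc, columns=cell_lines)
    return FoldChangeTable(
        logfc=logfc,
        mean_logfc=logfc.mean(axis=1),
        pseudocount=float(pseudocount),
        group_sizes=pd.DataFrame(sizes).T.rename_axis("cell_line"),
        treated=treated,
        untreated=untreated,
    )


def expression_logfc(
    values: pd.DataFrame,
    samples: pd.DataFrame,
    treated: str,
    untreated: str,
) -> FoldChangeTable:
    """Per-cell-line log2 fold-changes from an already-log2 expression matrix.

    For matrices on log2 scale (e.g. processed microarray data) the
    fold-change is the difference of condition means of log2 values; no
    pseudocount applies.  Missing entries are dropped from the means.
    """
    samples = samples.loc[values.columns]
    relevant = samples[samples["condition"].isin([treated, untreated])]
    if relevant.empty:
        raise ValueError(f"no samples with condition '{treated}' or '{untreated}'")
    cell_lines = sorted(relevant["cell_line"].unique())
    logfc = {}
    sizes = {}
    for line in cell_lines:
        in_line = relevant[relevant["cell_line"] == line]
        t_ids = in_line.index[in_line["condition"] == treated]
        u_ids = in_line.index[in_line["condition"] == untreated]
        if len(t_ids) == 0 or len(u_ids) == 0:
            empty = treated if len(t_ids) == 0 else untreated
            raise ValueError(
                f"cell line '{line}' has zero samples in condition '{empty}'"
            )
        logfc[line] = values[t_ids].mean(axis=1) - values[u_ids].mean(axis=1)
        sizes[line] = {treated: len(t_ids), untreated: len(u_ids)}
    logfc = pd.DataFrame(logfc, columns=cell_lines)
    return FoldChangeTable(
        logfc=logfc,
        mean_logfc=logfc.mean(axis=1),
        pseudocount=0.0,
        group_sizes=pd.DataFrame(sizes).T.rename_axis("cell_line"),
        treated=treated,
        untreated=untreated,
    )


def consensus_fold(
    fc: FoldChangeTable, fold: float = 4.0, mode: str = "all"
) -> tuple[list[str], list[str]]:
    """Genes at least ``fold``-fold up (and down) across cell lines.

    ``mode``:

    * ``"all"`` (default) — |logfc| ≥ log2(fold) with consistent sign in
      *every* cell line (the consensus filter);
    * ``"any"`` — in at least one cell line;
    * ``"average"`` — on the cross-line mean logfc.

    Returns ``(up, down)`` gene lists; the two sets are disjoint by
    construction.
    """
    if fold <= 1:
        raise ValueError("fold threshold must be > 1")
    if fc.logfc.shape[1] < 1:
        raise ValueError("fold-change table has no cell lines")
    cut = np.log2(fold)
    lf = fc.logfc
    if mode == "all":
        up = lf.index[(lf >= cut).all(axis=1)]
        down = lf.index[(lf <= -cut).all(axis=1)]
    elif mode == "any":
        up = lf.index[(lf >= cut).any(axis=1)]
        down = lf.index[(lf <= -cut).any(axis=1)]
        both = up.intersection(down)
        up, down = up.difference(both), down.difference(both)
    elif mode == "average":
        up = fc.mean_logfc.index[fc.mean_logfc >= cut]
        down = fc.mean_logfc.index[fc.mean_logfc <= -cut]
    else:
        raise ValueError(f"unknown mode '{mode}'")
    return list(up), list(down)


# the field-standard name: a fourfold cut is the default
def consensus_fourfold(fc: FoldChangeTable, fold: float = 4.0, mode: str = "all"):
    return consensus_fold(fc, fold=fold, mode=mode)


def logfc_distribution(fc: FoldChangeTable, n_grid: int = 256) -> pd.DataFrame:
    """Decile and kernel-density summary of the logfc distribution per cell line.

    Returns a tidy frame with one row per (cell line, statistic): the deciles
    q0..q100 and the Gaussian-KDE density evaluated on a common grid (columns
    ``grid`` and ``density`` hold arrays).  Requires at least 10 genes.
    """
    if fc.logfc.shape[0] < 10:
        raise ValueError("need at least 10 genes to summarize a distribution")
    lo = float(np.nanmin(fc.logfc.to_numpy()))
    hi = float(np.nanmax(fc.logfc.to_numpy()))
    pad = 0.05 * (hi - lo) if hi > lo else 1.0
    grid = np.linspace(lo - pad, hi + pad, n_grid)
    rows = []
    qs = np.linspace(0, 1, 11)
    for line in fc.cell_lines:
        x = fc.logfc[line].dropna().to_numpy()
        deciles = np.quantile(x, qs)
        density = (
            stats.gaussian_kde(x)(grid) if np.ptp(x) > 0 else np.full_like(grid, np.nan)
        )
        row = {"cell_line": line, "n": len(x)}
        row.update({f"q{int(100 * q)}": d for q, d in zip(qs, deciles)})
        row["grid"] = grid
        row["density"] = density
        rows.append(row)
    return pd.DataFrame(rows).set_index("cell_line")


def write_logfc_distribution(summary: pd.DataFrame, path) -> None:
    """Write the decile part of a distribution summary as TSV."""
    cols = ["n"] + [c for c in summary.columns if c.startswith("q")]
    summary[cols].reset_index().to_csv(path, sep="\t", index=False, float_format="%.6f")
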