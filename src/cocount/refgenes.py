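"""Data-driven discovery of stable reference genes and panel design.

Candidate reference genes are found by ranking genes of a genome-wide log2
expression matrix by their standard deviation across *all* samples of all
conditions and cell lines pooled: a gene whose SD stays under a threshold
(default 0.25 log2 units) regardless of treatment is a normalization
candidate.  Candidates are then screened on the count panel itself for
sufficient expression — a gene lost in the background noise cannot anchor a
shift — and a measurement panel is designed by stratified sampling over the
(mean expression, mean log fold-change) plane, with normalization genes
picked flat-in-fold-change but spread across the expression range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .diffexpr import FoldChangeTable
from .normalization import NormalizationResult

DEFAULT_SD_THRESHOLD = 0.25
DEFAULT_FC_CAP = 0.25


@dataclass
class StabilityReport:
    """Per-gene expression stability across all samples.

    ``table`` has one row per assessable gene, sorted by ascending SD (ties:
    descending mean expression, then gene name), with columns ``sd``,
    ``mean_expr``, ``n_obs`` and ``stable``; ``excluded`` lists genes that
    could not be assessed, with a reason.
    """

    table: pd.DataFrame
    threshold: float
    excluded: pd.DataFrame

    @property
    def stable_genes(self) -> list[str]:
        return list(self.table.index[self.table["stable"]])


def stability_screen(
    expr: ExpressionMatrix,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    max_missing: float = 0.5,
    by_group: str | None = None,
) -> StabilityReport:
    """Rank genes by cross-sample SD of log2 expression; stable ⇔ SD < threshold.

    SD uses denominator n−1 over the non-missing values of each gene, pooled
    across every sample (all conditions and cell lines).  The threshold is a
    strict inequality: a gene with SD exactly at the threshold is not stable.
    Genes observed in fewer than 2 samples, or missing in more than
    ``max_missing`` of samples, are excluded and listed with the reason.

    ``by_group`` ("condition" or "cell_line") additionally reports the
    maximum within-group SD in a ``max_group_sd`` column; stability calls
    remain based on the pooled SD.
    """
    if sd_threshold <= 0:
        raise ValueError("sd_threshold must be > 0")
    values = expr.values
    n_samples = values.shape[1]
    n_obs = values.notna().sum(axis=1)
    missing_frac = 1.0 - n_obs / n_samples

    reasons = {}
    for gene in values.index:
        if n_obs[gene] < 2:
            reasons[gene] = "observed in fewer than 2 samples"
        elif missing_frac[gene] > max_missing:
            reasons[gene] = f"missing fraction {missing_frac[gene]:.2f} > {max_missing}"
    excluded = pd.DataFrame(
        {"reason": pd.Series(reasons, dtype=object)}
    ).rename_axis("gene")

    keep = values.index.difference(excluded.index, sort=False)
    kept = values.loc[keep]
    table = pd.DataFrame(
        {
            "sd": kept.std(axis=1, ddof=1, skipna=True),
            "mean_expr": kept.mean(axis=1, skipna=True),
            "n_obs": n_obs.loc[keep],
        }
    ).rename_axis("gene")
    table["stable"] = table["sd"] < sd_threshold

    if by_group is not None:
        if by_group not in ("condition", "cell_line"):
            raise ValueError("by_group must be 'condition' or 'cell_line'")
        groups = expr.samples[by_group]
        per_group = pd.DataFrame(
            {
                g: kept.loc[:, groups.index[groups == g]].std(axis=1, ddof=1)
                for g in groups.unique()
            }
        )
        table["max_group_sd"] = per_group.max(axis=1)

    table = (
        table.reset_index()
        .sort_values(
            ["sd", "mean_expr", "gene"], ascending=[True, False, True], kind="mergesort"
        )
        .set_index("gene")
    )
    return StabilityReport(table=table, threshold=sd_threshold, excluded=excluded)


def expression_screen(
    candidates: list[str],
    norm: NormalizationResult,
    floor: float | None = None,
) -> tuple[list[str], list[str]]:
    """Partition reference-gene candidates into (usable, too_low) on the panel.

    A candidate is ``too_low`` when its median normalized linear count across
    samples is below ``floor``, or when it is missing (at or below
    background) in any sample.  The default floor is twice the pooled mean
    negative-control count — i.e. a candidate must clear the measured noise
    floor with some margin.
    """
    missing = [g for g in candidates if g not in norm.linear_values.index]
    if missing:
        raise ValueError(f"candidate(s) absent from panel: {missing}")
    if floor is None:
        floor = 2.0 * float(norm.background.mean())
    usable: list[str] = []
    too_low: list[str] = []
    for gene in candidates:
        row = norm.linear_values.loc[gene]
        if row.isna().any() or float(row.median()) < floor:
            too_low.append(gene)
        else:
            usable.append(gene)
    return usable, too_low


@dataclass
class PanelDesign:
    """A designed measurement panel: genes with roles and strata.

    ``table`` has one row per selected gene with columns ``role``
    ("target" or "normalization"), ``mean_expr``, ``mean_logfc``,
    ``expr_bin`` and ``fc_bin``.
    """

    table: pd.DataFrame
    n_expr_bins: int
    n_fc_bins: int

    @property
    def targets(self) -> list[str]:
        return list(self.table.index[self.table["role"] == "target"])

    @property
    def normalization_genes(self) -> list[str]:
        return list(self.table.index[self.table["role"] == "normalization"])


def _grid_bins(x: pd.Series, n_bins: int) -> pd.Series:
    """Equal-width bins over the observed range; constant input → single bin."""
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        return pd.Series(0, index=x.index)
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(x.to_numpy(), edges[1:-1]), 0, n_bins - 1)
    return pd.Series(idx, index=x.index)


def design_panel(
    expr: ExpressionMatrix,
    fc: FoldChangeTable,
    n_targets: int,
    n_norm: int,
    n_expr_bins: int = 8,
    n_fc_bins: int = 8,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    fc_cap: float = DEFAULT_FC_CAP,
    seed: int | np.random.Generator = 0,
) -> PanelDesign:
    """Design a targeted panel spanning the expression x fold-change plane.

    Targets are drawn by stratified sampling over the grid of
    (mean expression, mean log2 fold-change) bins: every occupied stratum
    gets one pick first, the remainder is allocated proportionally to
    stratum size with leftovers going to the densest strata.  Normalization
    genes are chosen from the stable (SD < ``sd_threshold``) genes that are
    also flat (|mean logFC| < ``fc_cap``): one per expression quantile bin
    where available, highest expression first, so the set spans the
    expression range.  A shortfall of flat stable genes yields a partial
    design with a warning.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    shared = expr.values.index.intersection(fc.mean_logfc.index)
    if n_targets + n_norm > len(shared):
        raise ValueError(
            f"requested {n_targets + n_norm} genes but only {len(shared)} have "
            "both expression and fold-change values"
        )
    mean_expr = expr.values.loc[shared].mean(axis=1, skipna=True)
    mean_logfc = fc.mean_logfc.loc[shared]
    ok = mean_expr.notna() & mean_logfc.notna()
    mean_expr, mean_logfc = mean_expr[ok], mean_logfc[ok]

    stability = stability_screen(expr, sd_threshold=sd_threshold)
    stable = set(stability.stable_genes)
    flat = mean_logfc.index[(mean_logfc.abs() < fc_cap)]
    norm_pool = [g for g in flat if g in stable]

    # normalization genes: one per expression quantile bin, highest first
    chosen_norm: list[str] = []
    if norm_pool:
        pool_expr = mean_expr.loc[norm_pool]
        q = pd.qcut(pool_expr.rank(method="first"), q=min(n_norm, len(norm_pool)),
                    labels=False)
        for b in sorted(set(q), key=lambda b: -pool_expr[q == b].max()):
            if len(chosen_norm) >= n_norm:
                break
            in_bin = pool_expr[q == b].sort_values(ascending=False)
            chosen_norm.append(in_bin.index[0])
    if len(chosen_norm) < n_norm:
        warnings.warn(
            f"only {len(chosen_norm)} of {n_norm} requested normalization genes "
            f"available (stable with |mean logFC| < {fc_cap})",
            stacklevel=2,
        )

    # targets: stratified over the (expression, logFC) grid
    target_pool = mean_expr.index.difference(chosen_norm, sort=False)
    expr_bin = _grid_bins(mean_expr.loc[target_pool], n_expr_bins)
    fc_bin = _grid_bins(mean_logfc.loc[target_pool], n_fc_bins)
    strata = pd.DataFrame({"expr_bin": expr_bin, "fc_bin": fc_bin})
    groups = strata.groupby(["expr_bin", "fc_bin"]).groups
    sizes = {k: len(v) for k, v in groups.items()}
    order = sorted(sizes, key=lambda k: (-sizes[k], k))

    alloc = {k: 0 for k in sizes}
    if n_targets >= len(sizes):
        for k in sizes:
            alloc[k] = 1
        remaining = n_targets - len(sizes)
        total = sum(sizes.values())
        fractional = {}
        for k in order:
            extra = remaining * (sizes[k] / total)
            take = min(int(np.floor(extra)), sizes[k] - alloc[k])
            alloc[k] += take
            fractional[k] = extra - take
        shortfall = n_targets - sum(alloc.values())
        for k in sorted(fractional, key=lambda k: (-fractional[k], -sizes[k], k)):
            if shortfall == 0:
                break
            if alloc[k] < sizes[k]:
                alloc[k] += 1
                shortfall -= 1
        # any residue (strata exhausted): fill from densest strata with room
        for k in order:
            while shortfall > 0 and alloc[k] < sizes[k]:
                alloc[k] += 1
                shortfall -= 1
    else:
        # fewer targets than occupied strata: take the densest ones
        for k in order[:n_targets]:
            alloc[k] = 1

    chosen_targets: list[str] = []
    for k, n_k in alloc.items():
        if n_k == 0:
            continue
        members = list(groups[k])
        picks = rng.choice(len(members), size=n_k, replace=False)
        chosen_targets.extend(members[i] for i in sorted(picks))

    all_expr_bin = _grid_bins(mean_expr, n_expr_bins)
    all_fc_bin = _grid_bins(mean_logfc, n_fc_bins)
    rows = []
    for gene in chosen_targets:
        rows.append((gene, "target"))
    for gene in chosen_norm:
        rows.append((gene, "normalization"))
    table = pd.DataFrame(rows, columns=["gene", "role"]).set_index("gene")
    table["mean_expr"] = mean_expr.loc[table.index]
    table["mean_logfc"] = mean_logfc.loc[table.index]
    table["expr_bin"] = all_expr_bin.loc[table.index]
    table["fc_bin"] = all_fc_bin.loc[table.index]
    return PanelDesign(table=table, n_expr_bins=n_expr_bins, n_fc_bins=n_fc_bins)
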