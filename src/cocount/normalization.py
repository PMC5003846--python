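"""Reference-gene anchored normalization of targeted count-panel data.

The procedure has four steps, applied per run:

1. **Background subtraction** — the mean count of the negative-control probes
   in each sample (or pooled across samples) is subtracted from every
   endogenous and housekeeping count.  Corrected values may be ≤ 0.
2. **log2 transform with masking** — corrected values ≤ 0 are undefined under
   the log and become missing (NaN); positive values become log2(value).
   Values that are negative after background subtraction are just as
   undefined as zeros, so the mask covers all of ``value <= 0``.
3. **Reference-gene shift** — a single additive offset d_j per sample on the
   log2 scale, chosen so the reference genes line up with their cross-sample
   means.  This is the least-squares solution of the one-way model
   ``x_gj ≈ m_g + d_j`` over the reference genes (simple regression with the
   gene mean as offset): with ``m_g`` the mean log2 value of reference gene g
   across the samples where it is defined,

       d_j = mean over reference genes defined in sample j of (x_gj − m_g)

   and the shift ``x'_gj = x_gj − d_j`` is applied to *all* probes.
   An additive log2 offset is equivalent to a per-sample multiplicative scale
   on counts, which is what differences in loaded RNA amount produce.
4. **Back-transform** — normalized linear counts ``2**x'`` wherever defined.

Missing entries only ever accumulate: nothing downstream unmasks a value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PanelRun


@dataclass
class NormalizationResult:
    """Output of the normalization pipeline.

    Attributes
    ----------
    log_values
        Normalized log2 values, genes x samples, NaN where undefined.
    linear_values
        ``2**log_values`` where defined, NaN elsewhere.
    shift
        Per-sample offset d_j (log2 units) that was subtracted.
    background
        Per-sample negative-control mean b_j (count units) that was
        subtracted; zero when normalization started from a log matrix.
    refgenes_used
        Reference genes the shift was anchored on.
    """

    log_values: pd.DataFrame
    linear_values: pd.DataFrame
    shift: pd.Series
    background: pd.Series
    refgenes_used: list[str]


def subtract_background(
    run: PanelRun, pooled: bool = False
) -> tuple[pd.DataFrame, pd.Series]:
    """Subtract the mean negative-control count from endogenous/housekeeping counts.

    Returns the corrected matrix (float; may contain values ≤ 0, which are
    *not* truncated here) and the per-sample background b_j.  With
    ``pooled=True`` a single background, the mean over all negative-control
    entries of all samples, is used for every sample.
    """
    negatives = run.negative_counts
    if negatives.shape[0] < 1:
        raise ValueError("panel has no negative-control probe")
    if pooled:
        level = float(negatives.to_numpy().mean())
        background = pd.Series(level, index=run.counts.columns, dtype=float)
    else:
        background = negatives.mean(axis=0).astype(float)
    background.name = "background"
    corrected = run.counts.loc[run.measured_genes].astype(float).sub(background, axis=1)
    return corrected, background


def log2_with_na(corrected: pd.DataFrame) -> pd.DataFrame:
    """log2-transform, masking undefined (≤ 0) entries as missing."""
    arr = corrected.to_numpy(dtype=float)
    out = np.full_like(arr, np.nan)
    positive = arr > 0
    out[positive] = np.log2(arr[positive])
    return pd.DataFrame(out, index=corrected.index, columns=corrected.columns)


def refgene_shift(
    log_values: pd.DataFrame,
    refgenes: list[str],
    background: pd.Series | None = None,
) -> NormalizationResult:
    """Align samples on reference genes via the least-squares per-sample shift.

    ``refgenes`` must all be present in ``log_values`` and each must be
    defined in at least one sample; a sample in which every reference gene is
    missing cannot be shifted and raises an error naming it.
    """
    refgenes = list(refgenes)
    missing = [g for g in refgenes if g not in log_values.index]
    if missing:
        raise ValueError(f"reference gene(s) not in matrix: {missing}")
    if not refgenes:
        raise ValueError("empty reference gene list")

    ref = log_values.loc[refgenes]
    never_defined = ref.index[ref.isna().all(axis=1)].tolist()
    if never_defined:
        raise ValueError(
            f"reference gene(s) missing in every sample: {never_defined}"
        )
    gene_means = ref.mean(axis=1, skipna=True)          # m_g
    residuals = ref.sub(gene_means, axis=0)
    shift = residuals.mean(axis=0, skipna=True)          # d_j
    dead = shift.index[shift.isna()].tolist()
    if dead:
        raise ValueError(
            f"sample(s) with all reference genes missing: {dead}"
        )
    shift.name = "shift"
    normalized = log_values.sub(shift, axis=1)
    if background is None:
        background = pd.Series(0.0, index=log_values.columns, name="background")
    return NormalizationResult(
        log_values=normalized,
        linear_values=np.power(2.0, normalized),
        shift=shift,
        background=background,
        refgenes_used=refgenes,
    )


def normalize(
    run: PanelRun | pd.DataFrame,
    refgenes: list[str],
    probe_class: pd.Series | None = None,
    pooled_background: bool = False,
) -> NormalizationResult:
    """Run the full pipeline: background → log2 with masking → reference shift.

    ``run`` is either a :class:`~cocount.containers.PanelRun` or a plain
    genes x samples matrix of (possibly non-integer) counts accompanied by a
    ``probe_class`` series — the latter form exists so normalized linear
    values can themselves be re-normalized, e.g. to verify idempotence.
    """
    if isinstance(run, pd.DataFrame):
        if probe_class is None:
            raise ValueError("probe_class is required when passing a raw matrix")
        negatives = run.loc[probe_class.index[probe_class == "negative"]]
        if negatives.shape[0] < 1:
            raise ValueError("panel has no negative-control probe")
        if pooled_background:
            background = pd.Series(
                float(negatives.to_numpy().mean()), index=run.columns, dtype=float
            )
        else:
            background = negatives.mean(axis=0).astype(float)
        background.name = "background"
        keep = probe_class.index[probe_class.isin(["endogenous", "housekeeping"])]
        corrected = run.loc[keep].astype(float).sub(background, axis=1)
    else:
        corrected, background = subtract_background(run, pooled=pooled_background)
    log_values = log2_with_na(corrected)
    return refgene_shift(log_values, refgenes, background=background)
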