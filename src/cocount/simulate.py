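"""Synthetic co-culture expression data with known ground truth.

The generator emulates the two kinds of input the pipeline consumes:

* a targeted count panel — endogenous counts are negative-binomial around
  ``f_j * (mu_g * 2**(delta_gc * treat(j)) * (1 - pi_j) + pi_j * marker_g)``
  with per-sample lane factor ``f_j`` (loading differences), per-gene base
  mean ``mu_g``, per-cell-line treatment effect ``delta_gc`` (log2),
  contamination fraction ``pi_j`` mixing in an effector-cell marker
  signature at the mean level, and dispersion ``phi``
  (variance = m + phi * m**2); negative-control probes are Poisson with
  per-sample rate ``lambda_j``;
* a processed genome-wide log2 expression matrix — values are
  ``log2(mu_g) + delta_gc * treat(j) + Normal(0, sigma_g)`` with
  ``sigma_g = 0.05`` for stable genes and log-normal (median 0.7 log2
  units, sigma_log 0.2) for variable genes, plus optional missing entries.

Defaults mirror the study design: three melanoma cell lines under
untreated / CTL co-culture / cytokine conditions; a panel of 185 target
genes plus 8 housekeeping candidates of which 3 sit at background level;
T-cell markers CD3D/CD3E/CD3G/CD8A/CD8B absent from tumor cells but strong
in the contaminant signature.  Treatment-responsive genes model strong
cytokine-induced programs: effect magnitudes are drawn Uniform(3, 6) log2
(8- to 64-fold) with per-line jitter, the regime of interferon-response
genes.  Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ExpressionMatrix, PanelRun

DEFAULT_CELL_LINES = ("Me275", "Me290", "T1185B")
DEFAULT_CONDITIONS = ("untreated", "CTL", "cytokines")
DEFAULT_TREATED = ("CTL", "cytokines")
MARKER_SIGNATURE = {
    "CD3D": 2000.0,
    "CD3E": 1500.0,
    "CD3G": 800.0,
    "CD8A": 1200.0,
    "CD8B": 900.0,
}
#: Housekeeping candidates, high to low expression; the last three are
#: planted at background level and should fail the expression screen.
HK_USABLE = ("RPLP0", "GUSB", "ALG12", "ADAT2", "KRBA2")
HK_LOW = ("DIRC1", "SLC26A3", "PHKG1")


def make_design(
    cell_lines: tuple[str, ...] = DEFAULT_CELL_LINES,
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS,
    replicates: int = 1,
) -> pd.DataFrame:
    """Sample sheet for a full cross of cell lines x conditions x replicates."""
    if replicates < 1:
        raise ValueError("need at least 1 replicate per condition")
    rows = []
    for line in cell_lines:
        for cond in conditions:
            for rep in range(1, replicates + 1):
                rows.append((f"{line}_{cond}_r{rep}", cond, line))
    design = pd.DataFrame(rows, columns=["sample_id", "condition", "cell_line"])
    return design.set_index("sample_id")


@dataclass
class SimulationTruth:
    """Ground truth behind a simulated dataset.

    ``gene_params`` has per-gene columns ``base_mean`` (linear counts),
    ``gene_class`` (stable / null / responder_up / responder_down / marker /
    housekeeping / housekeeping_low), ``sigma`` (log2 noise SD for the
    expression matrix) and ``marker_mean`` (contaminant signature);
    ``effects`` holds the per-cell-line true log2 effects delta_gc.
    Per-sample series are aligned to ``samples``.
    """

    gene_params: pd.DataFrame
    effects: pd.DataFrame
    samples: pd.DataFrame
    lane_factor: pd.Series
    background_rate: pd.Series
    contamination: pd.Series
    dispersion: float
    treated_conditions: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if (self.lane_factor <= 0).any():
            raise ValueError("lane factors must be positive")
        if (self.background_rate < 0).any():
            raise ValueError("background rates must be non-negative")
        if ((self.contamination < 0) | (self.contamination >= 1)).any():
            raise ValueError("contamination fractions must lie in [0, 1)")
        stable = self.gene_params.index[self.gene_params["gene_class"] == "stable"]
        if not (self.effects.loc[stable] == 0).all().all():
            raise ValueError("stable genes must have zero effects in every cell line")

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "gene_params": {
                "index_name": self.gene_params.index.name,
                "index": list(self.gene_params.index),
                "columns": list(self.gene_params.columns),
                "data": self.gene_params.to_numpy().tolist(),
            },
            "effects": {
                "index_name": self.effects.index.name,
                "index": list(self.effects.index),
                "columns": list(self.effects.columns),
                "data": self.effects.to_numpy().tolist(),
            },
            "samples": {
                "index_name": self.samples.index.name,
                "index": list(self.samples.index),
                "columns": list(self.samples.columns),
                "data": self.samples.to_numpy().tolist(),
            },
            "lane_factor": self.lane_factor.to_dict(),
            "background_rate": self.background_rate.to_dict(),
            "contamination": self.contamination.to_dict(),
            "dispersion": self.dispersion,
            "treated_conditions": list(self.treated_conditions),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SimulationTruth":
        def frame(block):
            index = pd.Index(block["index"], name=block.get("index_name"))
            return pd.DataFrame(block["data"], index=index, columns=block["columns"])

        samples = frame(payload["samples"])
        order = samples.index
        return cls(
            gene_params=frame(payload["gene_params"]),
            effects=frame(payload["effects"]).astype(float),
            samples=samples,
            lane_factor=pd.Series(payload["lane_factor"]).loc[order].astype(float),
            background_rate=pd.Series(payload["background_rate"]).loc[order].astype(float),
            contamination=pd.Series(payload["contamination"]).loc[order].astype(float),
            dispersion=float(payload["dispersion"]),
            treated_conditions=tuple(payload["treated_conditions"]),
            seed=int(payload["seed"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "SimulationTruth":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _check_design(design: pd.DataFrame) -> pd.DataFrame:
    for col in ("condition", "cell_line"):
        if col not in design.columns:
            raise ValueError(f"design lacks a '{col}' column")
    if design.index.has_duplicates:
        raise ValueError("duplicate sample ids in design")
    if len(design) == 0:
        raise ValueError("empty design")
    return design


def panel_truth(
    design: pd.DataFrame | None = None,
    seed: int = 0,
    n_targets: int = 185,
    n_up: int = 30,
    n_down: int = 10,
    dispersion: float = 0.1,
    effect_range: tuple[float, float] = (3.0, 6.0),
    effect_jitter: float = 0.2,
    lane_sdlog: float = 0.3,
    background_range: tuple[float, float] = (5.0, 15.0),
    contaminate: dict[str, float] | None = None,
    treated_conditions: tuple[str, ...] = DEFAULT_TREATED,
) -> SimulationTruth:
    """Ground truth for a study-like targeted panel.

    ``n_targets`` endogenous target genes (log-uniform base means 2^4..2^12,
    of which ``n_up``/``n_down`` are strong responders with per-line effects
    |delta| ~ Uniform(*effect_range*) log2, base means 2^7..2^12), the eight
    housekeeping candidates (five usable across the expression range, three
    at background level), and the five T-cell markers at zero tumor-cell
    expression.  ``contaminate`` maps sample ids to contamination fractions.
    """
    if design is None:
        design = make_design()
    design = _check_design(design)
    if n_up + n_down > n_targets:
        raise ValueError("more responders than targets")
    rng = np.random.default_rng(seed)
    cell_lines = sorted(design["cell_line"].unique())

    targets = [f"TGT{i:04d}" for i in range(1, n_targets + 1)]
    base = 2.0 ** rng.uniform(4.0, 12.0, size=n_targets)
    classes = np.array(["null"] * n_targets, dtype=object)
    responders = rng.choice(n_targets, size=n_up + n_down, replace=False)
    up, down = responders[:n_up], responders[n_up:]
    classes[up], classes[down] = "responder_up", "responder_down"
    base[responders] = 2.0 ** rng.uniform(7.0, 12.0, size=len(responders))

    hk_base = {"RPLP0": 4000.0, "GUSB": 1200.0, "ALG12": 400.0, "ADAT2": 150.0,
               "KRBA2": 60.0}
    genes = (
        targets + list(HK_USABLE) + list(HK_LOW) + list(MARKER_SIGNATURE)
    )
    gene_params = pd.DataFrame(
        index=pd.Index(genes, name="gene"),
        data={
            "base_mean": np.concatenate(
                [
                    base,
                    [hk_base[g] for g in HK_USABLE],
                    [1.0] * len(HK_LOW),
                    [0.0] * len(MARKER_SIGNATURE),
                ]
            ),
            "gene_class": (
                list(classes)
                + ["housekeeping"] * len(HK_USABLE)
                + ["housekeeping_low"] * len(HK_LOW)
                + ["marker"] * len(MARKER_SIGNATURE)
            ),
            "sigma": 0.0,
            "marker_mean": 0.0,
        },
    )
    # log2 noise for the companion expression matrix: tight for housekeeping
    # candidates, moderate for null targets, wide for responders
    gene_params.loc[gene_params["gene_class"].isin(["housekeeping", "housekeeping_low"]),
                    "sigma"] = 0.05
    gene_params.loc[gene_params["gene_class"] == "null", "sigma"] = np.exp(
        rng.normal(np.log(0.3), 0.3, size=(classes == "null").sum())
    )
    n_resp = len(responders)
    gene_params.loc[gene_params["gene_class"].isin(["responder_up", "responder_down"]),
                    "sigma"] = np.exp(rng.normal(np.log(0.3), 0.3, size=n_resp))
    for marker, level in MARKER_SIGNATURE.items():
        gene_params.loc[marker, "marker_mean"] = level

    effects = pd.DataFrame(0.0, index=gene_params.index, columns=cell_lines)
    for idx, sign in ((up, 1.0), (down, -1.0)):
        for i in idx:
            magnitude = rng.uniform(*effect_range)
            jitter = rng.normal(0.0, effect_jitter, size=len(cell_lines))
            effects.loc[targets[i]] = sign * (magnitude + jitter)

    lane_factor = pd.Series(
        np.exp(rng.normal(0.0, lane_sdlog, size=len(design))), index=design.index
    )
    background_rate = pd.Series(
        rng.uniform(*background_range, size=len(design)), index=design.index
    )
    contamination = pd.Series(0.0, index=design.index)
    for sample, pi in (contaminate or {}).items():
        if sample not in contamination.index:
            raise ValueError(f"contaminated sample '{sample}' not in design")
        contamination[sample] = pi

    return SimulationTruth(
        gene_params=gene_params,
        effects=effects,
        samples=design,
        lane_factor=lane_factor,
        background_rate=background_rate,
        contamination=contamination,
        dispersion=dispersion,
        treated_conditions=tuple(treated_conditions),
        seed=int(seed),
    )


def genomewide_truth(
    design: pd.DataFrame | None = None,
    seed: int = 0,
    n_stable: int = 100,
    n_variable: int = 900,
    n_up: int = 60,
    n_down: int = 30,
    stable_sigma: float = 0.05,
    sigma_log_median: float = 0.7,
    sigma_sdlog: float = 0.2,
    effect_range: tuple[float, float] = (1.0, 5.0),
    treated_conditions: tuple[str, ...] = DEFAULT_TREATED,
) -> SimulationTruth:
    """Ground truth for a genome-wide expression matrix.

    ``n_stable`` genuinely stable genes (log2 SD ``stable_sigma``) among
    ``n_variable`` variable genes whose SDs are log-normal around
    ``sigma_log_median``; ``n_up``/``n_down`` of the variable genes also
    carry treatment effects spanning ``effect_range`` (log2), so fold-change
    space is populated.
    """
    if design is None:
        design = make_design(conditions=("untreated", "CTL"), replicates=2)
    design = _check_design(design)
    if n_up + n_down > n_variable:
        raise ValueError("more responders than variable genes")
    rng = np.random.default_rng(seed)
    cell_lines = sorted(design["cell_line"].unique())

    stable = [f"STB{i:04d}" for i in range(1, n_stable + 1)]
    variable = [f"VAR{i:04d}" for i in range(1, n_variable + 1)]
    genes = pd.Index(stable + variable, name="gene")
    gene_params = pd.DataFrame(
        index=genes,
        data={
            "base_mean": 2.0 ** rng.uniform(3.0, 12.0, size=len(genes)),
            "gene_class": ["stable"] * n_stable + ["null"] * n_variable,
            "sigma": np.concatenate(
                [
                    np.full(n_stable, stable_sigma),
                    np.exp(rng.normal(np.log(sigma_log_median), sigma_sdlog, n_variable)),
                ]
            ),
            "marker_mean": 0.0,
        },
    )
    effects = pd.DataFrame(0.0, index=genes, columns=cell_lines)
    responders = rng.choice(n_variable, size=n_up + n_down, replace=False)
    for pos, i in enumerate(responders):
        sign = 1.0 if pos < n_up else -1.0
        magnitude = rng.uniform(*effect_range)
        effects.loc[variable[i]] = sign * (
            magnitude + rng.normal(0.0, 0.2, size=len(cell_lines))
        )
        gene_params.loc[variable[i], "gene_class"] = (
            "responder_up" if sign > 0 else "responder_down"
        )

    return SimulationTruth(
        gene_params=gene_params,
        effects=effects,
        samples=design,
        lane_factor=pd.Series(1.0, index=design.index),
        background_rate=pd.Series(0.0, index=design.index),
        contamination=pd.Series(0.0, index=design.index),
        dispersion=0.0,
        treated_conditions=tuple(treated_conditions),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance m + dispersion * m^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    positive = mean > 0
    if dispersion > 0:
        r = 1.0 / dispersion
        p = r / (r + mean[positive])
        out[positive] = rng.negative_binomial(r, p)
    else:
        out[positive] = rng.poisson(mean[positive])
    return out


def expected_panel_mean(truth: SimulationTruth) -> pd.DataFrame:
    """Noise-free expected endogenous/housekeeping counts, genes x samples."""
    samples = truth.samples
    treat = samples["condition"].isin(truth.treated_conditions).astype(float)
    mu = truth.gene_params["base_mean"].to_numpy()[:, None]
    delta = truth.effects[samples["cell_line"]].to_numpy()
    pi = truth.contamination.to_numpy()[None, :]
    marker = truth.gene_params["marker_mean"].to_numpy()[:, None]
    f = truth.lane_factor.to_numpy()[None, :]
    mean = f * (mu * 2.0 ** (delta * treat.to_numpy()[None, :]) * (1.0 - pi) + pi * marker)
    return pd.DataFrame(mean, index=truth.gene_params.index, columns=samples.index)


def simulate_panel(
    truth: SimulationTruth,
    design: pd.DataFrame | None = None,
    n_negative_probes: int = 8,
    rng: np.random.Generator | None = None,
) -> PanelRun:
    """Draw a targeted-panel count run from the truth.

    Endogenous and housekeeping counts are negative binomial around the
    expected means; negative-control probes are Poisson(lambda_j).
    Housekeeping-candidate genes carry the ``housekeeping`` probe class.
    """
    if design is not None and not design.equals(truth.samples):
        raise ValueError("design does not match the truth's sample sheet")
    if rng is None:
        rng = np.random.default_rng([truth.seed, 1])
    samples = truth.samples
    mean = expected_panel_mean(truth)
    counts = pd.DataFrame(
        _nb_sample(rng, mean.to_numpy(), truth.dispersion),
        index=mean.index,
        columns=mean.columns,
    )
    neg_names = [f"NEG_{chr(ord('A') + i)}" for i in range(n_negative_probes)]
    neg = pd.DataFrame(
        rng.poisson(
            np.broadcast_to(
                truth.background_rate.to_numpy()[None, :],
                (n_negative_probes, len(samples)),
            )
        ),
        index=pd.Index(neg_names, name="gene"),
        columns=samples.index,
    )
    counts = pd.concat([counts, neg])
    probe_class = pd.Series("endogenous", index=counts.index)
    hk = truth.gene_params.index[
        truth.gene_params["gene_class"].isin(["housekeeping", "housekeeping_low"])
    ]
    probe_class.loc[hk] = "housekeeping"
    probe_class.loc[neg_names] = "negative"
    return PanelRun(counts=counts, probe_class=probe_class, samples=samples.copy())


def simulate_expression_matrix(
    truth: SimulationTruth,
    design: pd.DataFrame | None = None,
    missing_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Draw a processed log2 expression matrix from the truth.

    Covers every gene with positive base mean (marker probes with zero tumor
    expression have no well-defined log2 baseline and are left to the panel).
    Missing entries are injected completely at random at ``missing_rate``.
    """
    if design is not None and not design.equals(truth.samples):
        raise ValueError("design does not match the truth's sample sheet")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    if rng is None:
        rng = np.random.default_rng([truth.seed, 2])
    samples = truth.samples
    params = truth.gene_params[truth.gene_params["base_mean"] > 0]
    treat = samples["condition"].isin(truth.treated_conditions).astype(float).to_numpy()
    baseline = np.log2(params["base_mean"].to_numpy())[:, None]
    delta = truth.effects.loc[params.index, samples["cell_line"]].to_numpy()
    sigma = params["sigma"].to_numpy()[:, None]
    values = baseline + delta * treat[None, :] + rng.normal(0.0, 1.0, size=(len(params), len(samples))) * sigma
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values = np.where(mask, np.nan, values)
    frame = pd.DataFrame(values, index=params.index, columns=samples.index)
    return ExpressionMatrix(values=frame, samples=samples.copy())


def simulate_paired_platform_logfc(
    n_genes: int = 150,
    compression: float = 0.6,
    noise_a: float = 0.3,
    noise_b: float = 0.05,
    true_sd: float = 2.0,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Paired per-gene log fold-changes from two platforms measuring one truth.

    Platform b reads the true logfc nearly faithfully (noise ``noise_b``);
    platform a compresses it by the factor ``compression`` plus noise
    ``noise_a`` — the regime where an intensity-based platform understates
    ratios relative to a counting platform.  Returns (logfc_a, logfc_b, true).
    """
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"G{i:04d}" for i in range(1, n_genes + 1)], name="gene")
    true = pd.Series(rng.normal(0.0, true_sd, n_genes), index=genes)
    a = compression * true + rng.normal(0.0, noise_a, n_genes)
    b = true + rng.normal(0.0, noise_b, n_genes)
    return a, b, true
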