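# Methods

## The normalization model

A hybridization count panel reports integer molecule counts C_gj per probe g
and sample j, with dedicated negative-control probes measuring nonspecific
background and an amount-of-input effect that is multiplicative per sample.
The pipeline models a sample as

    C_gj ≈ f_j · μ_gj + b_j,

with f_j the per-sample scale (RNA loading, lane efficiency) and b_j the
additive background.  Normalization inverts this in three steps:

1. **Background**: b_j is estimated as the arithmetic mean of the sample's
   negative-control counts and subtracted from every endogenous and
   housekeeping count.  Corrected values may be ≤ 0 and are deliberately not
   truncated here.  An optional pooled mode (`pooled_background`) uses one
   mean over all samples' negatives instead; per-sample is the default
   because lane-level background varies.
2. **log2 with masking**: log2 is undefined at ≤ 0, so all corrected values
   ≤ 0 become missing (NaN).  Masking covers negative corrected values, not
   only exact zeros — both are equally undefined under the log; a count at
   or below background carries no usable signal.  The missing mask only ever
   grows downstream; nothing is imputed.
3. **Reference shift**: on log2 scale the multiplicative f_j becomes the
   additive offset d_j.  It is fitted over a reference-gene set R by least
   squares in the one-way model x_gj ≈ m_g + d_j with the gene means m_g
   held at their cross-sample values — "regression with the mean as offset".
   The closed form is d_j = mean_{g∈R defined in j}(x_gj − m_g), the unique
   least-squares shift; a reference gene missing in a sample is dropped from
   that sample's mean, and a sample in which every reference gene is missing
   is an error rather than a silent zero.  The shift is applied to all probe
   classes so controls can be inspected on the normalized scale.

Properties that follow (and are tested): idempotence (re-normalizing the
normalized output yields shifts of 0); exact absorption of per-sample scale
factors whose geometric mean is 1; for general factors, d_j rises by
log2(f_j)(1 − 1/n) and the whole matrix translates by the common constant
mean(log2 f) because the gene-mean anchor itself moves — relative structure
is always invariant.  Positive-control probes are parsed and carried but not
used: the normalization is anchored exclusively on reference genes.

## Reference-gene discovery

Stability is scored as the SD (denominator n−1) of log2 expression across
*all* samples pooled — every condition and cell line — so a gene regulated
by treatment in even one line is penalized.  The default threshold is
SD < 0.25 log2 units, strict at the boundary.  Genes observed in fewer than
2 samples or missing in more than half are excluded with a reason rather
than scored.  An optional per-group report (`by_group`) adds the maximum
within-condition or within-line SD without changing the stability call.

A stable gene is only usable for panel normalization if the panel can
actually see it.  The expression screen rejects candidates whose median
normalized linear count falls below a floor, or which are masked in any
sample.  The floor is tied to the measured noise: twice the pooled
negative-control mean by default, configurable.  No numeric floor is
canonical; anchoring it at 2× background makes "too low to use" mean "within
a factor of two of the noise".

Panel design stratifies the (mean expression × mean log fold-change) plane
into an equal-width grid: every occupied stratum receives at least one
target, the rest are allocated proportionally with remainders to the densest
strata, and picks within a stratum are uniform at random.  Normalization
genes come from the stable-and-flat pool (|mean logFC| < 0.25), one per
expression quantile bin, highest expression first, so the anchor set spans
the dynamic range.  A shortfall produces a partial design plus a warning —
a panel with too few anchors should be a loud condition, not an exception.

## Fold-changes and the consensus filter

Fold-changes are computed on normalized *linear* counts (2^x′): condition
means first, then pseudocount k = 10, then the ratio, then log2.  Because
adding a constant commutes with averaging, add-then-average and
average-then-add are identical; the implementation also computes
log2(mean_t + k) − log2(mean_u + k) as a difference of logarithms so that
swapping the condition labels negates every value bit-exactly.  Masked
values enter condition means as 0 counts: a gene at background is treated as
unexpressed, not as an absent sample.  |logFC| is non-increasing in k, which
is the pseudocount's purpose — a gene rising from 0 to 10 counts reads as
2-fold, not infinite.

The consensus filter calls a gene up if logFC ≥ log2 F in every cell line
(down analogously), with F = 4 by default.  This is the conservative reading
of "at least F-fold across all lines"; `mode="any"` and `mode="average"`
(threshold on the cross-line mean) are provided because the gene count is
sensitive to that reading.

## Contamination and concordance QC

Effector-cell carry-over in sorted tumor-cell samples is screened via
T-cell markers (CD3D, CD3E, CD3G, CD8A, CD8B).  The background threshold is
B = mean + k·SD (k = 2, configurable) pooled over all negative-control
entries after applying each sample's normalization scale 2^(−d_j), so
markers and threshold share a scale; verdicts are therefore invariant under
global count rescaling and sample reordering.  Markers masked during
normalization count as 0 and pass.  No threshold for "how much CD3 is
tolerable" is assumed: every exceedance is reported with its magnitude.

Cross-platform concordance regresses platform a's per-gene logFC on
platform b's (OLS); slope < 1 quantifies compression of a relative to b, and
Pearson r summarizes agreement.  At least 3 shared finite genes are
required.  Note the slope estimates the true compression factor only when
platform b is nearly noise-free; noise in b attenuates the slope further
(classical errors-in-variables), which is the right behavior for a
compression *report* but means the slope is not a calibration constant.

## The synthetic-data generator

`simulate_panel` draws endogenous and housekeeping counts from a negative
binomial with mean f_j(μ_g · 2^{δ_gc·treat(j)} · (1−π_j) + π_j·marker_g)
and variance m + φm² (φ = 0.1 by default — overdispersion is the norm for
count panels), and negative controls from Poisson(λ_j).  Contamination is a
mixture at the mean level, sufficient to exercise the QC screen; no
read-level simulation.  `simulate_expression_matrix` writes
log2 μ_g + δ_gc·treat(j) + N(0, σ_g), σ_g = 0.05 for stable genes and
log-normal (median 0.7, σ_log 0.2) for variable genes, with optional
missing-completely-at-random entries.

Default study-like conditions: 3 cell lines × {untreated, CTL, cytokines},
185 target genes with log-uniform base means 2^4–2^12, eight housekeeping
candidates (five usable spanning ~60–4000 counts, three at background
level), five T-cell markers at zero tumor expression, lane factors
log-normal (σ_log 0.3), background rates uniform on 5–15 counts.
Treatment-responsive genes model strong cytokine-induced programs: effect
magnitudes Uniform(3, 6) log2 (8- to 64-fold, the regime of
interferon-response genes) with per-line jitter of SD 0.2 and base means
≥ 2^7, 30 up / 10 down among the targets.  With dispersion 0.1 and 3
replicates per condition, a per-line logFC estimate has SD ≈ 0.4; effects
at the 4-fold calling boundary would be recovered at chance level in each
line, so the planted responders sit clearly above it — recovery tests
measure the pipeline, not coin flips at the threshold.

What the generator does *not* emulate: probe-level sequence effects and
cross-hybridization, cartridge/batch structure, correlated gene programs
(genes are independent given the design), sorting-induced stress responses,
and microarray-specific intensity saturation.  Passing recovery tests
therefore shows the pipeline correctly inverts the generative model it
assumes — lane scaling, additive background, overdispersed counts, mean-level
contamination — not that real co-culture data obey that model.

## Numerical choices and degenerate inputs

* Counts must be non-negative integers at the container boundary; the
  normalization core accepts float matrices so its own linear output can be
  re-normalized (idempotence checks).
* Stability ties are broken by descending mean expression, then gene name,
  making reports deterministic; sample order never matters anywhere.
* Sample SD uses ddof = 1 throughout; a single-sample shift is 0 by
  construction (gene means equal the only observation).
* All randomness flows through `numpy.random.Generator` seeded from one
  integer; the same seed reproduces outputs bit-identically, and the truth
  record round-trips losslessly through YAML.
* Problem sizes in tests and the acceptance script (≈1000-gene expression
  matrices, ≈200–400-gene panels, 2–3 replicates) are chosen so each
  recovery statistic has comfortable sampling margin while the whole suite
  runs in seconds.

## Known limitations

* The per-sample background subtraction assumes negative controls share the
  background of endogenous probes; probe-specific background is not modeled.
* The stability screen is a pooled-SD ranking; pairwise-stability statistics
  in the geNorm/NormFinder family are out of scope.
* The consensus filter is a pure fold-change criterion with no variance
  moderation or error control — faithful to the screening workflow it
  implements, not a replacement for a test-based differential-expression
  analysis.
* The compression slope is descriptive (see errors-in-variables note above).
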