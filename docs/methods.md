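# Methods

## Model and assumptions

The pipeline assumes a cohort of samples partitioned into transcriptional
subtypes by an external nearest-template classifier, with log2-scale
expression matrices for mRNAs and microRNAs over the *same* samples. A
driver microRNA is modelled as (a) differentially expressed in its subtype,
(b) predicted to target genes of that subtype's UP or DOWN signature,
(c) mutually informative with those targets across the whole cohort, and
(d) able to explain a non-trivial fraction of the signature's expression in
a linear model. No single gate is treated as sufficient: each has a
calibrated null, and candidates must pass all four.

The regression view (gate 4) takes log2 target expression as approximately
linear in log2 microRNA expression — a first-order approximation that is
standard for both transcription-factor and microRNA regulation. Gate 3 makes
no parametric assumption at all: the mutual-information estimator operates
on ranks.

## Stage parameters (defaults and units)

| parameter | default | meaning |
|---|---|---|
| `core_fdr_max` | 0.05 | nearest-template FDR ceiling for core samples |
| `core_delta_percentile` | 95 | pooled-δ percentile; cores need δ strictly below it |
| `ks_p_threshold` / `fc_threshold` | 0.001 / 2.0 | gate-1 cut: bootstrap-KS p and absolute linear FC |
| `ks_n_boot` | 1000 | bootstrap resamples; the attainable p floor is 1/(n+1), so ≥1000 is required for p < 0.001 |
| `enrichment_thresholds` | auto | per-classifier (adjusted-p, O/E) pair minimizing the random-set FDR over a grid |
| `mi_p_target` | 1e-7 | tail probability defining the MI significance threshold |
| `n_boot_regulon` / `consensus_p` | 100 / 1e-12 | bootstrap networks and the binomial support cut for consensus edges |
| `sd_min` | 1.2 | s.d. filter on the quantile-normalized log2 scale (hub exempt) |
| `mra_percentile` | 95 | null-model percentile fixing the Fisher-p threshold |
| `slr_percentile` | 90 | percentile of pooled fractions fixing the gate-4 cut |

All expression values are log2; fold changes are linear
(FC = 2^(mean log2 difference)); "absolute FC > t" means FC > t or FC < 1/t,
strict at the boundary.

## Mutual information

MI is estimated with a fixed-bandwidth Gaussian kernel density on
copula-transformed data (average ranks mapped to (r−½)/n). The bandwidth is
h = 0.25·n^(−1/6) — the bivariate Silverman rate with the constant
calibrated once against the closed form −½·ln(1−ρ²) for bivariate Gaussian
data (maximum deviation ≈ 0.04 nats at n = 2000 over ρ ∈ {0.2, 0.5, 0.8}).
Because only ranks enter, the estimate is exactly symmetric and invariant
under strictly increasing transforms of either argument (decreasing
transforms agree to float summation order). Values are clamped at 0.

The significance threshold exploits that, after the copula transform, the
null distribution of the estimator depends only on n: the null is simulated
as MI between the fixed rank grid and random permutations of it, log(p) is
regressed on MI over the upper 1% tail, and the line is extrapolated to the
target probability (10⁻⁷ by default — far beyond direct permutation
counting). At a reachable target (10⁻³) the extrapolation agrees with the
direct empirical quantile within a few percent, and the threshold decreases
monotonically with n.

With a single imposed hub there are no indirect-path triplets, so the
data-processing-inequality pruning of general multi-hub network inference
has no role here and is not applied.

## Consensus regulons

Each bootstrap resamples samples with replacement and keeps hub–gene edges
above the MI threshold. Support counts are tested against
Binomial(n_boot, rate) with rate = total kept edges / (n_boot × n_genes) —
a random-edge-placement null — and edges with support p below `consensus_p`
are retained with their mean MI. Note the rate is estimated from the run
itself: at thresholds low enough to saturate the keeping rate the consensus
becomes unselective by construction, so the regulon-shrinks-with-threshold
monotonicity holds for bootstrap support always, and for the final edge set
in the non-saturated regime the defaults operate in.

## Stepwise regression

Bidirectional search from the full model, Gaussian AIC
(n·log(RSS/n) + 2k), ties within 1e-8 broken toward the smaller model;
candidate order does not affect the result. A perfect fit is floored at
RSS = 1e-12 to keep collinear degenerate inputs comparable. AIC admits an
unrelated regressor at the χ²(1) > 2 rate (≈ 15.7% per decoy); this is a
property of the stop criterion, not noise — the per-microRNA *fraction*
aggregation and the 90th-percentile threshold are what turn noisy per-gene
selections into a usable gate. The attribution fraction divides by the
number of the signature's genes present in the expression matrix, so genes
outside every regulon count as unselected and fractions are on the scale of
the whole signature.

Gate-4 fits use the original log2 matrices, not the network-preprocessed
ones: the preprocessing (linearize → quantile-normalize → re-log2) serves
the rank-based MI step and would only distort a linear fit.

## Null model for the master regulator test

Null microRNAs must be detected in more than 10% of samples (detection =
value above `detection_threshold`, default 0 on the log2 scale), have
|SNR| < 0.05 in every subtype contrast (SNR = group mean log2 difference
over the sum of group s.d.), and their regulons must overlap every candidate
regulon by less than 70% (overlap = shared / size of the smaller set). The
one-sided literal reading SNR < −0.05 — which selects negatively
differential microRNAs — is available via `snr_literal_negative`, but the
symmetric bound is the default since the null is meant to contain
*non*-differential microRNAs. When no microRNA qualifies, the Fisher-p
threshold falls back to 1e-4. If the null regulons are all empty the
resulting threshold is permissive and is flagged in the log.

## Synthetic data: what it emulates and what it does not

`simulate_dataset` plants `n_driver_micrornas` drivers, each downregulated
by `driver_shift` (default −1.5 log2) in its subtype, with
`n_targets_in_signature` target genes inside the subtype's UP signature and
a few off-signature targets, generated as baseline + slope·(microRNA −
mean) + N(0, noise_sd) with slope −0.8 and noise s.d. 0.5. Non-target
signature genes carry a microRNA-independent ±1 log2 subtype shift; decoy
microRNAs and non-signature genes are subtype-independent. MicroRNA
per-sample s.d. is 1.5 and gene s.d. is drawn from U(0.8, 2.2), so the 1.2
s.d. network filter removes a realistic share of genes while driver targets
survive it. Classification FDRs are low for ~90% of samples and δ follows a
Beta(2, 5), so the FDR and percentile core rules are both exercised.

Everything is Gaussian on the log2 scale: no counts, no mean–variance
relationship, no stromal admixture, no batch structure, and identifiers are
exact strings. Passing tests therefore demonstrate the pipeline's gating,
calibration and reproducibility logic — not robustness to RNA-seq noise
models or annotation mismatches.

## Problem sizes used in tests and the acceptance script

The reference synthetic runs use 3 subtypes × 60 samples, 600 genes and 60
microRNAs, with 50 regulon bootstraps, 200 randomized-set iterations and
2×10⁴ null MI values; the estimator oracles use n = 2000 (MI), n = 450 ×
50–100 replicates (stepwise), and 200–500 replicates (KS calibration).
These sizes give stable results for the planted effect sizes; the full-scale
defaults (100 bootstraps, 1000 iterations, 10⁵ null MIs) remain the
configuration defaults.

## Numerical choices and edge cases

- Percentiles use linear interpolation between order statistics throughout;
  δ and fraction thresholds are strict inequalities, and degenerate
  all-equal distributions (which a strict rule then fails entirely) are
  logged.
- `ks_boot` uses +1 smoothing, p = (1 + #{D* ≥ D})/(1 + n_boot), and
  canonicalizes its argument order so p is exactly symmetric; tied values
  are handled by evaluating the ECDF difference at tie-run ends.
- The KS fold change is computed from log2 means (a geometric-mean fold
  change on the linear scale).
- The Bonferroni family in gate 2 is the number of (microRNA, signature)
  tests within a classifier.
- The enrichment/MRA universe defaults to the intersection of the
  expression gene space with the target map's gene space (configurable).
- Identifier matching is exact string match after upper-casing; missing
  expression values are a hard error by default with an opt-in
  drop-feature policy.
- Every stochastic step derives a child seed from the single run seed via
  a seed sequence; the manifest records all of them, and repeated runs with
  the same configuration are bit-identical.

## Known limitations

- Fold-change-based gates assume roughly symmetric group sizes; very small
  subtype cores lower the bootstrap-KS resolution (p floor 1/(n_boot+1)).
- The kernel MI estimator is biased downward for strong dependence at small
  n; the bootstrap consensus compensates operationally but MI values should
  be compared within a run, not across cohorts.
- The binomial consensus null conditions on the run's own edge-keeping
  rate; see above for the saturation caveat.
- Subtype-level correlation consolidation requires ≥ 4 subtypes.
- The pipeline attributes association, not causality; "driver" status needs
  the downstream silencing-based procedures or equivalent experiments.
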