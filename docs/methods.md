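# Methods

## The model

For each gene g the package fits the weighted linear model

    y_g = X beta_g + eps_g,   Var(eps_gs) = sigma_g^2 / w_gs,

where y_g are normalized log2-CPM values over all pooled samples, X is the
samples x k design matrix (explicit intercept, a 0/1 class indicator, and
optional covariate / batch-indicator columns), and the precision weights
w_gs come from the voom mean-variance trend. Residual variances are shrunk
toward a scaled inverse-chi-square prior (d0, s0^2) fitted by the
closed-form moment method on the log variances, and the tested coefficient
yields a moderated t with d0 + (n - k) degrees of freedom, a two-sided
p-value, and a Benjamini-Hochberg adjusted p-value. A gene is called
differentially expressed when |log2 FC| > 1 and adjusted p < 0.05 (both
strict).

The point of the package is that no party ever pools y_g. K clients hold
disjoint sample cohorts; every pooled quantity the fit needs is a sum of
local statistics, and each sum is assembled by a three-party protocol:

* clients send noisy parameters M_i' to an **aggregator** and the noise
  N_i to a separate **compensator**;
* non-negative integer parameters use additive secret sharing over the
  prime field Z_p, M_i' = (M_i + N_i) mod p with N_i uniform on Z_p — the
  aggregate is exact provided sum_i M_i < p (enforced structurally by
  arbitrary-precision integer arithmetic), and a single noisy share is
  exactly uniform, i.e. leaks nothing;
* real parameters use Gaussian masking M_i' = M_i + N_i with
  N_i ~ N(0, sigma^2); the mutual-information leak of one share is bounded
  by (1/2) log2(1 + var(M_i)/sigma^2) bits.

Defaults: p = 2^54 - 33 (the largest prime below 2^54) and sigma^2 = 1e12.
With these, masked and unmasked runs differ by < 1e-8 in p-values and
t-statistics (asserted in the acceptance tests). Roles are separated
structurally: the aggregator object only accepts masked messages, the
compensator only noise shares, and a full-run audit log lets tests assert
that no per-sample expression vector is ever transmitted.

## Pipeline stages and what is exchanged

1. **Expression filtering** (filterByExpr-style). A gene is kept iff its
   pooled total count strictly exceeds `min_total_count` (default 15) and
   at least `min_n_samples` samples have CPM >= `min_count` /
   median(library size) * 1e6 (default `min_count` 10), where CPM uses each
   sample's own raw library size and `min_n_samples` is the smallest pooled
   class size. Exchanged: per-gene totals and pass counts, class-indicator
   column sums (masked integers). The pooled **median library size** is
   found by bisection on the integer value range; each step exchanges one
   masked count of samples at or below the pivot (2 log2(total reads) ~ 60
   scalar rounds). The large-sample `min.prop` adjustment and tolerance
   factors of the reference filter are deliberately not replicated; only
   the two rules above are.
2. **Upper-quartile normalization.** Per sample, the UQ statistic is the
   75th percentile (type-7 linear interpolation) of counts/library-size
   over kept genes; factors are rescaled to geometric mean 1 across pooled
   samples using one masked sum of logs and one masked sample count. TMM is
   intentionally out of scope (it would require disclosing a reference
   sample profile). Library sizes are computed over all genes before
   filtering; UQ statistics over kept genes only.
3. **log-CPM** is purely local: log2((count + 0.5) / (lib * factor + 1) * 1e6).
4. **Two-pass fit.** Pass 1 fits with unit weights via one masked X^T X and
   per-gene masked X^T y, computes per-gene residual SD from masked SSE
   sums (the plain, unweighted SSE), and fits the mean-variance trend:
   LOWESS (span 0.5, 3 robustifying iterations, delta = 1% of the x-range)
   of sqrt(residual SD) against average log2 count (mean log2-CPM shifted
   by the pooled mean log2 effective library size — one extra masked scalar
   round). Clients turn the broadcast trend into weights
   w = trend(fitted log2 count)^-4, clamping interpolation to the knot
   range so weights stay finite; trend values are floored at 1e-6. Pass 2
   refits with these weights (per-gene masked X^T W X, X^T W y) and uses
   the *weighted* SSE so the residual variance matches the weighted
   regression the moderated t assumes — pass 1 keeps the plain
   sum-of-squares definition.
5. **Inference** runs entirely on the aggregator from global statistics:
   moment-method prior fit (trigamma inverse by safeguarded Newton,
   relative tolerance 1e-8; if the excess dispersion of log variances is
   <= 0 the prior is degenerate, d0 = infinity, and the prior variance is
   the arithmetic mean of the sample variances), moderated t, BH step-up.
   No prior trend (eBayes trend=FALSE behavior) and no fold-change
   shrinkage; logFC is the raw coefficient in log2-CPM units. With
   d0 = infinity the normal tail replaces the Student tail.

Run with a single client the same code path is the centralized pipeline;
this defines the pooled oracle used everywhere in testing. The centralized
path is additionally cross-validated against Bioconductor limma/edgeR
(upper-quartile factors, voom, lmFit, eBayes) through an Rscript test;
agreement is ~1e-10 in logFC, t and log10 p on a 400-gene dataset, so the
1e-6 test tolerance is comfortable.

The unscaled standard error is sqrt(diag((X^T W X)^-1)) — the definition
under which the moderated t reproduces the reference implementation (the
alternative reading diag(X^T X) does not).

## Numerical and protocol choices

- Noise streams are derived per (run seed, client index, CRC32 of round
  name, repetition counter), so runs are reproducible and no stream is
  reused across rounds.
- A pooled design with condition number > 1e12 is rejected as collinear; a
  design column that is nonzero for exactly one pooled sample is refused
  outright (its coefficient would expose that sample's profile) — only the
  masked per-column nonzero counts are inspected.
- The global gene universe is the intersection of client gene lists in
  client-1 order; dropped genes are logged.
- Masked-sum cancellation can leave a residual SSE of order -1e-10 where
  the true value is 0; SSE is clamped at 0 before the square root.
- Batch effects across m cohorts are handled by m-1 reference-coded
  dataset-indicator columns appended consistently to every design
  (`add_batch_indicators`); cohort 0 is the reference level.

## Meta-analysis baselines

Each cohort is analyzed alone by the centralized pipeline; results are
restricted to genes surviving the filter in every cohort. Fisher
(-2 sum ln p, chi-square with 2K df) and Stouffer (weights sqrt(n_i))
combine one-sided halves split by the sign of the local fold change, and
the final two-sided p is min(1, 2 min(p_up, p_down)) — opposite-direction
effects cancel rather than reinforce, matching directional meta-analysis
practice. REM is DerSimonian-Laird with tau^2 clamped at 0 and per-cohort
effect variance (unscaled SE * posterior SD)^2 — the moderated SE being
the natural per-cohort uncertainty available. Rank Product ranks genes
within cohorts by fold change, takes the geometric mean of ranks per
direction, and estimates p by within-cohort rank permutation (default
1000 permutations, add-one corrected, null pooled across genes; the same
permutation set serves both directions so up/down p-values are exactly
symmetric under sign flip). Global fold change for all combiners except
REM is the unweighted mean of local fold changes.

Evaluation against the pooled oracle reports RMSE and Pearson/Spearman
correlation on -log10 raw p (floored at 1e-300) and precision / recall /
F1 / FP / FN on the DE-call sets.

## Synthetic data

The generator emulates a two-class bulk RNA-seq study: gene baselines
log2-CPM ~ N(5, 2^2); gene-wise NB dispersions log-normal around 0.1
(Var = mu + phi mu^2), which makes the mean-variance trend non-trivial; a
planted fraction (default 10%) of genes receives +-2 log2 fold change with
random sign; small age-like (continuous, centered) and sex-like (binary)
covariate effects on 20% / 10% of genes; library sizes uniform on
[1e6, 3e6]. Counts are drawn deterministically from the stored model given
the seed, which is what lets batch injection regenerate counts after
shifting NB means (zero shifts reproduce the original matrix bit for bit).

Cohort splitting apportions samples by largest remainder to the requested
size ratios (1:1:1, 1:2:4, 1:3:9 in the study scenarios), realizes
per-cohort class fractions within one sample, and can tilt cohort
assignment exponentially in the age covariate to emulate a cohort-level
confounder that is deliberately left out of the model.

What the simulation does *not* emulate: compositional library effects of a
full transcriptome (only ~2000 genes), outlier samples, correlated genes,
isoform structure, or single-cell dropout. Passing tests therefore show
protocol-level equivalence (federated = pooled, masked = unmasked) and
sane statistical behavior under NB sampling — not performance on any real
cohort.

## Problem sizes in the tests

The equivalence checks run at G = 2000 genes and n = 130-150 samples over
three cohorts — large enough that ~1800 genes survive filtering and a few
hundred DE calls are made, while the whole suite stays in the tens of
seconds. Property tests use 20-500 gene toys. The type-I check uses a
null simulation at G = 2000, n = 40 and requires the fraction of raw
p < 0.05 to sit within 3 binomial SEs of 0.05.

## Known limitations

- Single-coefficient tests only; no contrast matrices, no TREAT, no robust
  empirical Bayes, no sample-quality weights.
- The federated median protocol assumes integer library sizes (always true
  for counts).
- Honest-but-curious, non-colluding parties; no dropout/fault tolerance,
  no transport security (the bus is in-process by design).
- The moderated t with d0 = infinity uses the normal distribution rather
  than pooling residual df across genes; the branch is reachable only on
  degenerate inputs.
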