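# Methods

## The problem

DNA methylation arrays report a beta value — the fraction of methylated
signal, in [0, 1] — for each of ~485k CpG probes. Cohorts processed with
different normalization pipelines, or measured on different platforms
(array vs. whole-genome/reduced-representation bisulfite sequencing),
occupy visibly different regions of data space even when the underlying
biology matches, which blocks cross-dataset and cross-institution
analyses. This package addresses that by (1) compressing probe-level
betas into transcript-level features, (2) factorizing a large training
cohort under a gene-set prior so the latent variables carry biological
labels, and (3) freezing the latent matrix and re-expressing any new
cohort as loadings on it. In the shared loading space, pipeline- and
platform-specific distortions are attenuated while group structure
survives — the property the acceptance suite measures directly with
silhouette scores.

## Probe-to-transcript compression

Promoter methylation is the signal of interest, so for each transcript we
keep the probes within 1500 bp of the TSS (symmetric window by default;
a strand-aware upstream-only flag reproduces the array's TSS1500
convention; a first-exon mode selects on the `1stExon` region tag
instead). Each transcript's probes-by-samples block is mean-centered per
probe and decomposed by SVD with samples as observations; we retain the
smallest leading set of principal components whose cumulative
explained-variance fraction reaches the threshold (default 0.8). The
retained eigenvectors and training means are the reusable model: new
cohorts are centered with the *training* means and projected with the
stored eigenvectors, so every cohort lands in the identical feature
space. A mean or median per promoter would be simpler but collapses the
spatial methylation pattern; multiple PCs keep distal-vs-proximal
contrasts that a location summary discards.

Numerical choices:

- Missing betas: probes with more than 20% missing entries are dropped
  from the transcript before PCA; remaining gaps are imputed at the
  probe's observed mean. At projection time, probes absent from the new
  data are imputed at the training mean (zero contribution after
  centering) and counted.
- Eigenvector signs are fixed so the largest-magnitude element is
  positive, making archives byte-stable across runs and platforms.
- An all-constant transcript keeps one zero-variance component
  (explained variance defined as 1) so the transcript survives into the
  feature space.
- The cumulative-variance comparison is >=, so an exactly attainable
  threshold is accepted.
- Covariance (not correlation) PCA on centered, unscaled betas: probes
  are already on a common [0, 1] scale, and per-probe rescaling would
  inflate near-constant probes.

## Knowledge matrix

Gene sets arrive as GMT files; symbols are uppercased and deduplicated,
and colliding set names across files are source-prefixed. Membership is
gene-level, so every PC feature of every transcript of a gene inherits
the gene's memberships — the only expansion consistent with filtering the
compressed matrix by the prior's gene list. Sets overlapping fewer than
`min_genes = 10` *distinct* genes are dropped (counting distinct genes,
not feature rows, keeps multi-transcript genes from inflating support).
Features whose gene appears in no retained set are dropped by default,
together with the matching data rows.

## Constrained factorization

Given the compressed matrix D (features x samples, rows z-scored by
default) and the binary prior C (features x sets), the solver seeks

    min  ||D - Z B||_F^2 + lambda1 ||Z - C U||_F^2
         + lambda2 ||B||_F^2 + lambda3 P(U)
    s.t. Z >= 0, U >= 0

with P(U) an elastic net, P(U) = a ||U||_1 + (1-a)/2 ||U||_2^2 at
`l1_fraction` a = 0.9 (pure L1 at a = 1). The strict positivity of the
mathematical statement is implemented as the closed set >= 0; strict
positivity is unattainable with sparse solutions.

Per iteration (order B -> Z -> U):

- B-step: exact ridge minimizer (Z'Z + lambda2 I)^-1 Z'D — never
  increases the objective, which the tests assert at 1e-10 slack.
- Z-step: the unconstrained ridge minimizer
  (D B' + lambda1 C U)(B B' + lambda1 I)^-1 clipped at zero. Clipping can
  in principle break monotonicity; the suite allows 1e-8 relative slack
  and observes none beyond it.
- U-step: per LV column, non-negative elastic-net coordinate descent on
  ||z_j - C u||^2 + (lambda3/lambda1) P(u) (the prior term carries the
  lambda1 weight in the full objective). Columns whose support exceeds
  `max_path = 10` are truncated to the largest coefficients and refitted
  on that support. A warm start from the previous iterate is kept
  whenever the new candidate scores worse, so the U step is monotone by
  construction.

Defaults and rationale:

- `lambda2 = sigma_k(D)`, `lambda1 = lambda2 / 2` when "auto": tying the
  ridge weights to the k-th singular value keeps the penalties
  commensurate with the reconstruction term at any data scale. Both are
  overridable.
- `lambda3` "auto" runs a geometric search: start at the median column
  kill-threshold (the penalty at which a column's U zeroes out) and halve
  it between short rounds until at least `frac = 0.7` of LVs carry a
  prior association, then freeze. Only lowering lambda3 keeps the
  recorded objective trace monotone across the switch. An up-and-down
  variant was evaluated and brought no recovery benefit.
- Convergence: relative change of the penalized objective below
  `tol = 1e-6`, capped at `max_iter = 350`. The recorded trace is the
  elastic-net objective actually minimized; the four-term form with pure
  L1 is available from `objective()` for reporting.
- Initialization is closed-form (positive part of the scaled truncated
  SVD; dead columns re-seeded from absolute values), so fits are
  bit-reproducible given identical inputs.
- k is user-supplied; no automatic latent-dimension selection is
  attempted.

## Transfer decomposition and downstream analyses

A new cohort, compressed with the stored eigenvectors and standardized
with the training row means/SDs, is decomposed against the frozen Z by
the same ridge solve as the B-step. Everything downstream operates on B
or on probe betas:

- Ward hierarchical clustering on Euclidean distances (scipy linkage).
- Hartigan–Wong k-means (max 100 iterations, 10 restarts, best
  within-cluster SS kept) — implemented directly since Python libraries
  ship Lloyd's algorithm only.
- UMAP with neighbors = 15, components = 2, epochs = 200, Euclidean
  metric, fixed random state.
- Per-LV differential tests: Welch two-sample t (a pooled-variance flag
  exists), two-sided p, Benjamini–Hochberg step-up q across all k LVs.
  Welch is the safer default when the sidedness and variance assumptions
  of the original analyses are unstated.
- Two-group log-rank test (lifelines): observed vs. hypergeometric
  expected events per distinct event time, statistic (ΣO-ΣE)^2/ΣV,
  chi-square with 1 df.
- DMP calling: per-probe Welch t on betas over a probe subset, BH across
  the tested probes, direction (hypo/hyper) relative to a named reference
  group, `none` on exactly tied means.

BH families follow the per-analysis convention: LV tests adjust over the
k LVs, DMP tests over the tested probe subset.

## Platform liftover

Bisulfite calls (chrom, 1-based position, beta or methylated/total
counts) are joined onto the probe manifest by exact coordinate: a probe
matches the CpG cytosine at its own position or at position + 1 (the
reverse-strand cytosine of the dinucleotide). Opposite-strand calls are
combined by a coverage-weighted mean, which always lies between the two
per-strand betas. Count-based sites below `min_total = 5` are set
missing; the threshold is ignored for beta-only input. The coverage
report (matched fraction, per-chromosome counts) is the diagnostic that
separates well-covered WGBS conversions from sparse RRBS ones. Genome
assembly remapping is out of scope; inputs must share an assembly label
(or pass `force`).

## Synthetic data

The generator inverts the pipeline so every stage has a known truth:
sparse non-negative U (each LV owns a distinct primary set; supports
overlap pairwise by at most one set so the planted factors stay mutually
distinguishable), Z = C U plus half-normal noise, group-structured B (two
groups, half the LVs shifted by +-2), gene signal G = Z B + N(0,
noise_sd), and probe betas through an inverse-logit link with slope 1.5,
per-probe offsets N(0, 0.5), and per-probe logit-scale measurement noise
with SD equal to noise_sd. The measurement noise is what makes
per-transcript PCA non-degenerate (without it every transcript collapses
to one perfect component); setting noise_sd = 0 removes it too, so a
noiseless simulation yields perfectly rank-correlated probes within a
gene. Default conditions: 120 genes x 1 transcript x 6 probes, 12 gene
sets, k = 6, 80 samples, noise_sd = 0.3, seed 17.

What the generator does not emulate: array chemistry (type I/II probe
bias), preprocessing artifacts, missingness patterns, cell-type
composition, or genuine genomic correlation structure. Passing tests
demonstrate algorithmic correctness and the bias-reduction mechanism
under controlled distortions — not performance on real cohorts.

Survival fixtures are exponential event times with a hazard ratio
between two groups and independent exponential censoring whose rate is
set from the target censoring fraction.

## Problem sizes

Test and acceptance runs use the default fixture above (720 probes, 80
samples, ~135 retained features after knowledge filtering), 500-replicate
null calibration for the log-rank test at n = 50 + 50, and exhaustive
small-instance oracles elsewhere. These sizes were chosen so the entire
suite exercises every pipeline stage in well under a minute per run while
keeping each statistical check adequately powered.

## Known limitations

- Latent-factor recovery at a sharp matched-correlation cutoff is
  seed-sensitive on noisy fixtures; the subspace is found reliably
  (high mean matched correlation) but individual correlated factors can
  fall below a 0.9 cutoff on some draws.
- The Z-step's clip-after-solve is a heuristic for the non-negativity
  constraint, not a projected solve; monotonicity is empirical (and
  asserted) rather than guaranteed.
- Exact-coordinate liftover does no fuzzy matching and no assembly
  remapping.
- No cross-validated significance scoring of LV–gene-set associations is
  provided; U's support is a sparsity pattern, not a calibrated
  enrichment statistic.
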