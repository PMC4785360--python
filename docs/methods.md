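# Methods

This note records the statistical models, the choices made where the design
was genuinely open, and what the synthetic benchmarks do and do not show.

## Per-gene association scan

Each gene is fit by ordinary least squares against drug sensitivity plus
the confounders (age and three genotype PCs as numeric covariates; sex,
batch, cancer type and tissue type as factors, dummy-encoded against the
lexicographically first level). The design matrix is shared across genes,
so the scan is a single linear solve for all genes at once; a
1,000-permutation null or a 100-replicate subsampling power curve therefore
costs seconds, not hours.

Numerical conventions:

* A sample enters a drug's scan only when its sensitivity and every
  covariate are present; missing data never drop rows at parse time.
  Per-drug sample counts may therefore differ.
* Constant numeric covariates are dropped (they alias the intercept);
  single-level factors contribute no columns.
* A rank-deficient design (for example a batch perfectly aliased with
  sensitivity) flags the affected genes with undefined p-values rather than
  raising.
* A perfect fit (zero residual variance, detected at relative tolerance
  1e-12) reports p = 0 with a `degenerate` flag; genes with exactly
  constant expression are flagged `zero_variance` and excluded from the
  multiple-testing family.
* Plain OLS standard errors are used — no robust/sandwich correction — as
  the model is specified as ordinary linear regression.

Benjamini–Hochberg is implemented directly (step-up, capped at 1, NaNs
excluded from the family) and cross-checked against
`statsmodels.stats.multitest.multipletests` in the tests. DRA calls use
FDR ≤ 0.1; sign classes come from the sign of the sensitivity coefficient.

**Permutation null.** Sensitivity labels are permuted across the drug's
usable samples, covariates staying attached to their samples, and the full
scan is re-run (default 1,000 times). The reported `frequency` counts
permutations whose significant-gene count *ties or beats* the observed
count. Counting ties is the conservative reading; a strict `>` rule is
available via `tie_rule="gt"`. On an all-null panel the observed count is 0
and every permutation ties it, so frequency = n_perm by convention.

## Grouping samples

Ward clustering uses `scipy.cluster.hierarchy.linkage(method="ward")` on
Euclidean distances between sample profiles over the DRA genes — the
merge-cost-equals-increase-in-within-cluster-sum-of-squares contract
(the "ward.D2" convention). The two-cluster cut with the higher mean
sensitivity is labelled sensitive. The trichotomy uses the sample standard
deviation (n−1); values exactly at mean ± k·SD go to the extreme classes
("at least k SD away" read inclusively). Because activity area is oriented
so that larger values mean a stronger response, an `invert_labels` switch
exposes the opposite naming without changing the partition.

## Overlap statistics

Top-k overlap sweeps compare two p-value-ranked gene lists (e.g. male vs
female strata) over the grid k = 100, 200, …, 5000 with a one-tailed
Fisher's exact test — the hypergeometric upper tail — flagged at p ≤ 0.05.
The universe is the set of genes tested in both strata (the defensible
choice when stratum-specific filtering differs). The gene-set
overrepresentation table uses the same kernel per set with BH across sets
at 0.05. Note that the hypergeometric null is discrete: with 50-gene sets,
a 50-gene query and a 5,000-gene universe the attainable
fraction of raw p ≤ 0.05 under the null is ≈ 0.014, not 0.05; the tests
compare against the enumerated reference rather than the nominal level.

## Modular differential connectivity

Pair connectivity is |Pearson r|, the minimal faithful reading of "mean
co-expression"; a soft-threshold power exponent (default 1) is exposed for
WGCNA-style variants. Modules are intersected with the measured genes and
dropped below 30 members. Indeterminate samples are excluded. With the
default 50 permutations the smallest nonzero FDR is 0.02.

The permutation FDR is one-sided *in the direction selected by the observed
MDC* (count larger MDCs when observed > 1, smaller when < 1). Under a true
null this selection doubles the tail mass: P(FDR ≤ α) ≈ 2α for small α,
because the observed statistic falls in either tail with equal probability
and each tail is tested at α. The calibration tests assert this 2α
behaviour; users comparing module FDRs to a nominal level should bear the
factor of two in mind. An observed MDC of exactly 1 reports direction
`neutral` with FDR 1. Cross-drug aggregation ranks each drug's modules —
significant ones (FDR ≤ 0.05) first by |log MDC| descending, then the rest
by FDR — and orders modules by ascending rank sum.

## Key-driver analysis

The candidate's own membership is *not* counted in its neighborhood B, and
the hypergeometric universe N is the analysis subnetwork (module plus 2-hop
fringe); both conventions are configurable (`include_self`,
`universe="network"`). The empirical FDR resamples |A| genes uniformly from
the subnetwork node set and counts how often a random module overlaps a
candidate's neighborhood at least as well; because the hypergeometric tail
is monotone in the overlap at fixed (N, K, n), this equals counting null
p ≤ observed p. This resampling null is a declared operationalisation (the
output header records it); it is conservative in practice — on random
modules it flags ~3% of candidates at the 5% threshold, because overlaps
are small integers and ties are frequent.

## Synthetic data

The generator inverts the analysis models, with defaults mirroring the
study panel they emulate:

| parameter | default | rationale |
|---|---|---|
| samples / genes | 323 / 20,069 | panel dimensions |
| sensitivity | Beta(2,5) scaled to [0, 7.8] | right-skewed activity areas on the observed range |
| donor age | Normal(53, 10) truncated at 18 | median donor age ~53 |
| sex | Bernoulli(1/2) | balanced by default |
| batch / cancer / tissue levels | 4 / 7 / 17 | panel composition |
| planted effect | γ giving partial correlation 0.4 | magnitude of clearly-correlated single genes |
| noise ε | N(0, 1) | expression units; effect sizes scale relative to it |
| module correlations | ρ_sensitive = 0.2, ρ_resistant = 0.7 | a strong connectivity-gain module |

Covariate coefficients are drawn per gene from centred normals with small
scales (age 0.01/yr, factors 0.3, PCs 0.2) so confounding is present but
does not dominate. Expression is exactly linear-Gaussian; module blocks are
equicorrelated Gaussian (MDC depends only on the mean pairwise
correlation, so equicorrelation is the sufficient structure); networks are
Barabási–Albert graphs (heavy-tailed degrees) with planted hubs wired
directly to 85% of one module's genes.

All randomness flows from one master `numpy.random.SeedSequence` spawned
into per-stage child streams in a fixed order, so each stage is
independently reproducible and adding genes does not perturb covariates.

What the generator does **not** emulate: heavy-tailed or heteroscedastic
expression noise, correlated background genes, realistic linkage between
tissue and cancer type, dose–response curve fitting (activity areas are
drawn directly), and copy-number or mutation structure. Passing tests
demonstrate correctness of the statistics under the stated model, not
robustness to real-data violations of it.

## Problem sizes in tests and the acceptance script

Recovery and calibration runs use panels of 200–2,000 genes and 150–300
samples, 20-seed replication, 50–100 permutations for the scan null and
200–500 for KDA; these sizes give stable Monte-Carlo estimates (binomial
standard errors below the asserted margins) while keeping the whole suite
under a minute of compute for the statistical checks. The pipeline's
defaults retain the full-scale constants (1,000 scan permutations, 50 MDC
permutations, the 100…5000 overlap grid).

## Known limitations

* The per-gene model is linear; non-linear sensitivity–expression
  relationships are invisible to it.
* Genotype PCs are taken as fixed input columns, not recomputed per drug
  subset.
* Expression is regressed as provided; no internal normalisation or log
  transform is applied.
* The MDC connectivity definition (absolute correlation, no topological
  overlap) is one of several in use; the soft-threshold exponent is the
  only exposed variant.
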