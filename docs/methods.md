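# Methods

## Scope and model

The package quantifies per-sample aneuploidy burden from segmented
copy-number data and relates it to immune cytolytic activity through
unfolded-protein-response (UPR) signaling. The computation has six stages,
each a pure function of its inputs; all randomness is driven by explicit
seeds.

### SCNA event model

A segment is characterized by its log2 intensity ratio `x`. Event counts
follow a two-threshold rule with *strict* inequalities: 1 event for
`0.1 < |x|`, 2 events for `1 < |x|`, else 0. Values sitting exactly on a
threshold are deliberately not events; this matters only on measure-zero
inputs but is pinned by tests.

Arms are scored on the fractional-length-weighted mean of their segments,
with segments clipped to the arm interval (clipping rather than
whole-assignment of centromere-spanning segments is a design choice; the
alternative changes only segments crossing the centromere). An arm with no
overlapping segment has no intensity evidence and cannot qualify; its
chromosome can then contribute at most arm-level events from the covered
arm.

Classification per chromosome: both arms qualifying with the same direction
→ whole-chromosome events, counted by applying the threshold rule to the
length-weighted whole-chromosome intensity (symmetric with the arm rule and
consistent with the 0–46 bound); otherwise each qualifying arm contributes
its own events. Focal events are counted independently of the larger
categories: every qualifying segment whose clipped extent is strictly
smaller than its arm's covered extent adds its event count. The extent
fraction (default 1.0, i.e. "anything shorter than the full covered arm")
is exposed as `focal_fraction` for sensitivity analysis. Extents are
measured in base pairs, not probe counts.

Category totals are min-max rescaled over the *pooled* cohort (all tumor
types together, matching the single pan-cancer score used downstream) and
summed into the combined score in [0, 3]. A category with zero cohort range
maps to 0 with a warning; cohorts of fewer than 2 samples are rejected.

### Expression scores

CYT is the geometric mean of GZMA and PRF1 on the log2(TPM+1) scale. The
input contract adds the +1 pseudocount so the matrix is finite and
non-negative; a pure log2(TPM) convention differs by a monotone reindexing
and does not change any rank-based downstream statistic.

P53 activity z-scores the 10-gene repressed signature within tumor type
(cohort-global z-scoring is available via a flag). Within-type scoring was
chosen because the score's downstream use is per-type correlation and
cross-type location differences would otherwise dominate. Zero-variance
genes get z = 0 with a warning. The negated sum is min-max rescaled to
[0, 1].

### Differential co-expression

Stratification takes low = score ≤ 30th percentile, high = score ≥ 70th
percentile within tumor type (numpy's linear percentile interpolation).
Adjacencies are Spearman matrices; constant genes yield 0 with a warning.
The pair statistic is `D = (½|sign(c_low)c_low² − sign(c_high)c_high²|)^β`
with β = 4 applied exactly as the outer exponent (the antecedent
differential-co-expression method uses β/2; the exponent is a function
argument, default 4). Since the permutation test compares D against its own
permutation distribution and D is a monotone transform of the inner
difference, the choice of exponent does not change p-values — it matters
only for reported effect sizes.

Permutation p-values use the positively biased estimator
`(1 + #{D_perm ≥ D_obs}) / (n_perm + 1)`, which cannot be zero; BH is
applied across the 1,653 unordered within-type pairs. Streams are seeded
per (tumor type, permutation index), so results are independent of
execution order. Statistics are computed on the upper triangle; the
full 58 × 58 = 3,364-cell matrix is what the pair-cell accounting reports.

A structural property worth knowing: with 1,000 permutations the smallest
achievable p is 1/1001, so after BH across 1,653 pairs a pair can only
reach q < 0.05 when at least 34 pairs of its tumor type sit jointly at the
minimal p. Recovery of planted structure therefore switches on per tumor
type; the planted design (40 pairs) sits deliberately above that threshold.

Pair classification: perturbed = permutation-q < 0.05 in ≥ 9 tumor types,
with direction by majority sign of `c_low − c_high` among significant types
(ties → mixed); preserved = stratum correlations BH-significant in *both*
strata of *every* analyzed type and not perturbed (the one-stratum variant
is a documented alternative; both-strata is the stricter reading). The
control-pathway empirical FDR reports the flagged fraction at both gene and
pair level.

### Pathway scores

Per tumor type and branch, a Lasso linear regression of the 0/1 tumor
indicator on branch-gene expression. Linear (not logistic) regression on
the binary response keeps the score an affine functional of expression.
Predictors are standardized before penalization; coefficients are reported
on both scales and scoring uses the original scale. The penalty is the
10-fold class-stratified CV-error minimizer; no one-standard-error rule is
applied. A consequence measured in the tests: under pure-noise labels the
min-CV rule keeps a stray gene in a minority of fits (median support ≤ 1,
~60% fully degenerate) rather than being empty ≥ 90% of the time — the 1-SE
rule would be more conservative but is not used here. All-zero fits are
flagged degenerate and excluded from scoring. The intercept is fit but
excluded from the score (it shifts all samples equally and cancels in rank
correlations).

### Association models

OLS uses explicit dummy coding against declared baselines (Stage I for
stage), listwise deletion with reported counts, and rejects rank-deficient
designs naming the aliased columns. Partial Spearman rank-transforms all
variables, residualizes the ranks on the controls by least squares and
correlates residuals, with t-based p on n − 2 − k degrees of freedom;
residuals that are numerically zero (controls explain everything) return
rho = 0 by convention. MSI-high is `msi_score ≥ 0.4` (the cutoff direction
is configurable). The SCNA-stratum expression test pools low samples across
tumor types against pooled high samples, with BH across genes. One BH
routine (`aneupr._stats.bh_adjust`) backs every correction in the package.

### Single-cell stage

`log2(TPM/10 + 1)` transform, Ward linkage on Euclidean distances over the
RIDD targets (scipy's tie-breaking by smallest cluster index makes the leaf
order reproducible for a fixed input order), and a two-sided Wilcoxon
rank-sum test on per-cell mean RIDD expression between tumor cells and
macrophages, excluding ITGB2 and TAPBP whose expression runs counter to
RIDD regulation. Two-sided testing is the conservative choice where the
expected direction (macrophages lower) is checked separately.

## Synthetic cohort generator

The generator emulates the statistical structure the analyses assume, with
every planted quantity exposed:

- **Events.** Per tumor sample, each chromosome is whole-chromosome-altered
  with probability 0.08·(1 + stage shift); otherwise each arm independently
  with 0.10·(1 + shift); focal events are Poisson(6·(1 + shift)). Stage
  shifts default to 0 / 0.5 / 0.55 / 0.8 for stages I–IV. Magnitudes are 1
  or 2 events with the corresponding log2FC bands (~±0.35, ~±1.5).
- **Realization.** Events become SEG segments: full-arm segments for
  whole-chromosome/arm events; short embedded segments for focal events,
  with lengths bounded so their contribution to the arm's weighted
  intensity stays below the event threshold (budget 0.06 per arm), and
  near-zero background fill elsewhere. This guarantees the SEG pipeline
  recovers the planted counts exactly — verified as a test invariant and in
  the acceptance run.
- **Co-expression.** Four disjoint 5-gene blocks among the 58 UPR genes
  (40 pairs) follow an equicorrelated one-factor model whose correlation
  switches between strata (low 0.7, high 0.1, middle interpolated) in 10 of
  12 tumor types; planted values are Spearman targets, realized through the
  Gaussian-copula inversion ρ_pearson = 2·sin(πρ/6). Stratum membership is
  determined after event realization by the same 30/70 rule the pipeline
  applies, so planted regimes align with what the pipeline estimates
  without label leakage.
- **CYT coupling.** GZMA and PRF1 share a latent variable coupled to the
  within-type normal scores of the planted burden at Spearman −0.3 (again
  via the copula inversion), plus small per-gene noise.
- **Pathways, TP53, MSI.** Tumors shift +1.5σ on the first half of each
  branch gene set; TP53-mutant probability rises with burden and mutants
  shift the repressed signature up; mutation counts are Poisson with
  log-rate +0.5·z(burden) in MSS and −0.5·z in MSI-H (5% MSI-H).
- **Sizes.** Defaults: 12 tumor types × 334 tumors + 30 normals. 334 makes
  the 30/70 split yield 100 samples per stratum — the group size at which
  the permutation/BH machinery has adequate per-pair power given the
  feasibility threshold described above; typical real tumor-type cohorts
  run 250–300 samples, so this is the upper-middle of the realistic range.
- **Single cell.** 1,257 tumor cells vs 119 macrophages; log-normal TPM
  with RIDD targets shifted down 1.5σ in macrophages (the two excluded
  counter-regulated genes shift up).

What the generator does **not** emulate: platform/batch effects, purity
contamination of segment means, realistic segment-length distributions,
gene–gene correlation outside the planted blocks, copy-number-driven
expression dosage, or single-cell dropout. Passing tests therefore
demonstrate correctness of the statistical machinery under the assumed
structure, not robustness to real-data artifacts.

## Problem sizes and numerical choices

The test suite and the acceptance script run the co-expression recovery at
the full default cohort (12 × 334, 1,000 permutations, ~20 s), the null
calibration on 528 exchangeable pairs, pathway recovery at 100 tumors /
100 normals per type, and the OLS design at 25 types × 6,000 samples × 20
seed replicates. The SEG-realization round-trip is checked on a 3-type
cohort; event classification is vectorized per chromosome so a full-size
realization remains feasible. The acceptance script averages the planted
co-expression recovery over three replicate cohorts and the Lasso sparsity
fraction over five replicate fits to reduce the variance of the reported
estimates; single-replicate values fluctuate (the per-type BH feasibility
switch is the dominant variance source).

Ties: percentile thresholds use linear interpolation; Spearman uses average
ranks; min-max scaling maps a zero-range category to 0. Degenerate inputs
(constant genes, empty strata, missing arms, all-zero models) produce
warnings or typed errors rather than NaNs, as specified per operation.

## Known limitations

- The bundled gene sets preserve the cardinalities the analysis depends on
  (58 UPR, 33 RIDD, 10 TP53-repressed, 2 CYT, 3 control pathways of 20) and
  use real human gene symbols, but branch memberships are illustrative, not
  a faithful export of the curated databases; the file is labelled
  synthetic.
- The recurrence rule's sensitivity is intrinsically switch-like (per-type
  BH feasibility), so single-seed recovery estimates have high variance.
- Whole-chromosome event magnitude thresholds the length-weighted
  whole-chromosome intensity; other conventions (e.g. max of arm counts)
  would differ for chromosomes with strongly asymmetric arm intensities.
- Pathway models do not transfer across tumor types, and no purity/ploidy
  correction of segment means is attempted.
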