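# Methods

This note records the statistical procedures, the synthetic-data model, the
numerical conventions, and the design choices that were genuinely open.

## Statistical kernels

All downstream stages run on four kernels (`core_stats`), each reporting the
method actually used (`exact` / `normal_approx`) and the effective sample
size after pairwise deletion of missing values.

**Spearman correlation.** ρ is the Pearson correlation of midranks
(tie-corrected). For n ≥ 10 the p-value uses the t approximation
t = ρ√((n−2)/(1−ρ²)) on n−2 degrees of freedom; for n < 10 the permutation
null of ρ is enumerated over all n! orderings of the midranks, which remains
valid under ties because the null conditions on the observed tie pattern.
The motor-neuron screens run at n = 11–14, i.e. on the asymptotic path; this
is recorded in the result metadata.

**Mann–Whitney U.** The statistic is U of the first sample. The null is
enumerated exactly over all C(n₁+n₂, n₁) labelings when n₁+n₂ ≤ 20 without
ties; otherwise the normal approximation with tie and continuity correction
is used. The threshold 20 is standard practice; the lymphoblastoid contrasts
(n ≈ 20–26) and the CSF comparison (n = 66) take the asymptotic path.

**Fisher enrichment.** One-sided over-enrichment only:
p = P(X ≥ overlap) for X hypergeometric on the gene universe. The workflow
prioritises modules by enrichment, never depletion, so the one-sided test is
the faithful reading. The universe defaults to all genes measured on the
platform after transcript→gene collapse and is configurable.

**Benjamini–Hochberg.** Step-up adjustment (via statsmodels), reported next
to raw p-values wherever a family of tests is run; selection in the screens
and prioritisation uses the *unadjusted* thresholds (0.01, 0.05, 5e-8),
because those are the thresholds the workflow specifies — every report
surfaces this.

**Principal components.** Scores are projections onto the leading
eigenvectors of the feature covariance (SVD after internal centring), with
the sign convention that each component's largest-magnitude loading is
positive. Requesting more components than the rank returns the available
ones with a warning.

## Synthetic-study generator

The generator (`synthetic`) emulates the two study designs the pipeline
consumes: a CNS arm (default 11 samples; microarray-scale 54,675 transcripts,
configurable — the test suite and the acceptance script use 2,000 and state
so here as the package's own problem size) and a blood arm (default 26
samples with rapid/slow/intermediate progression labels, durations < 2 y,
> 4 y, and 2–4 y respectively, in a 40/40/20 mix).

**Module model.** Each planted module is a single latent factor plus
independent Gaussian noise; the loading is set so the expected within-module
pairwise correlation equals the configured value (default 0.7). Factors are
orthogonalised in-sample (QR): at n ≈ 12 samples two independent N(0,1)
factors can correlate at |r| ≈ 0.6 by chance, which would genuinely merge
distinct planted modules and make recovery ill-posed; exact in-sample
orthogonality keeps the planted ground truth recoverable, which is the
generator's purpose (recovery testing, not realism).

**Couplings.** The pathology-linked module doubles as the "immune-like"
module: its CNS factor drives the pathology counts (Poisson with log link,
baseline 20 inclusions per unit area — counts are the natural covariate
type), inversely drives the CNS durations (rank-mapped onto the configured
range, with the duration noise residualised against all factors so no other
module acquires a chance duration association), and most of the planted
GWAS-like gene set is drawn from it. The progression-linked module carries a
blood group shift only; the control-identity module is coupled to nothing.

**Blood group shift.** In blood, linked modules carry the per-gene additive
shift (±group_effect/2 for rapid/slow) with conditionally independent noise;
their co-expression arises from the group structure itself. If the shift
instead rode on a shared latent factor, the factor's within-group variance
would cap the Bayes accuracy of *any* gene panel at ≈ 0.77 for
group_effect = 1.5, making multi-gene panels pointless; the additive design
lets panels aggregate evidence across genes, which is the property the blood
stage exists to measure. Blood factors of unlinked modules are orthogonal to
the group contrast for the same reason the CNS factors are orthogonalised.

**CSF generator.** Controls are lognormal around ≈ 7 ng/ml. The
`paper_like` profile gives cases a higher lognormal baseline, an early-stage
elevation (multiplier decaying linearly over the first quartile of
percent-of-course) and a positive duration coupling in the last quartile;
`null` draws cases from the control distribution. The profile was calibrated
once against the generator's stated contracts (case mean above control mean
in ≥ 95% of replicates; null profile calibrated to α) and then frozen.

**What the generator does not model.** Probe-level artefacts,
normalisation effects, batch structure, censored survival by default, and
realistic inter-module correlation. Passing tests therefore demonstrate that
the pipeline recovers the structure it assumes, not that real microarray
data satisfy those assumptions.

## Network stage conventions

- Unsigned network (|cor|^β): the classical default, matching
  similar-expression seeding; neighborhoods rank by *signed* correlation
  descending, since seeding looks for co-expression, not anti-correlation.
- Neighborhood size ⌈fraction·(N−1)⌉ per seed; the seed is excluded from its
  own ranking but always a node; correlation ties break by transcript
  identifier.
- Soft power: smallest β ∈ 1..20 whose scale-free fit R² (log-frequency vs
  log-connectivity over ten connectivity bins) reaches 0.8, else the argmax
  with a warning; ties take the smallest β.
- Module detection: average linkage on 1−TOM with a static cut at the 0.9
  quantile of merge heights. A cut at 0.99 was tried first and discarded —
  on seeded networks it leaves one giant cluster (recovery ARI ≈ 0). After
  the cut, clusters under 30 nodes dissolve into the unassigned pool, and a
  rescue pass in the spirit of dynamic tree cutting's PAM stage reassigns an
  unassigned node to its most similar surviving cluster when its mean TOM to
  that cluster reaches the cluster's 25th-percentile internal similarity.
  Cut quantile, minimum size and rescue percentile are all configurable;
  the defaults were fixed on development simulations before the acceptance
  checks were wired up.
- Recovery is evaluated (tests, acceptance script) as the adjusted Rand
  index over the *planted* transcripts present in the network. Background
  transcripts enter seeded neighborhoods precisely because they correlate
  with a module factor at the top-1% level — at 12 samples that is r ≈ 0.7,
  indistinguishable in-sample from true membership — so penalising their
  co-clustering would measure the sample size, not the method.

## Blood stage conventions

- Durations are rounded to the nearest half-year (producing ties, hence
  Efron's tie handling in the Cox partial likelihood, via lifelines); all
  subjects are treated as deceased unless a censoring column is supplied.
- Duration appears only as the outcome; covariates are onset age, sex and
  the module's top 15 expression PCs (truncated to n−1 with a warning).
  The model's significance is the likelihood-ratio χ² of the PC block
  against the covariates-only null, df = number of PCs. Zero-variance
  features are dropped first; a degenerate block yields χ² = 0, p = 1
  exactly. Collinear or non-convergent fits retry with a small ridge
  (penalizer 0.1) and are flagged.
- Logistic screens test each gene by likelihood ratio against the
  intercept-only null. (Quasi-)separation — likelihood within 1e-3 of its
  supremum or |β| > 30 — triggers a ridge-penalised refit (λ = 1) of both
  models and a flag, so screening never aborts at n ≈ 20.
- LOOCV panels standardise features on each training fold, fit with a small
  ridge (1e-2) for stability, and predict at probability 0.5. "Chance" is
  the exact binomial tail at 0.5 (a balanced coin); the majority-class
  baseline is reported alongside because the groups need not be balanced.

## CSF stage conventions

- The packaged table is transcribed from a published clinical table
  (46 sporadic ALS, 20 controls) and checksum-verified on load; an internal
  consistency check (sampling age ≈ onset + duration × percent/100) passes
  for all 45 staged rows. Control ages as printed cannot be parsed
  consistently; they are stored verbatim and excluded from every
  computation. The 309.6 ng/ml outlier is retained — rank-based testing is
  the outlier policy, not exclusion.
- Staging ranks the staged ALS subjects by percent of disease course at
  sampling and takes floor(centile·n) subjects per tail (11 of 45 at the
  default quartile). The floor convention is fixed because it reproduces the
  published stage means (36 and 13 ng/ml); the ceiling convention (12 per
  tail) does not (34/13).
- The two confirmatory tests are directional, matching their hypotheses:
  sTREM2 *elevated* in ALS (one-sided Mann–Whitney, p = 0.033; two-sided
  0.067 reported alongside) and *positive* late-stage duration association
  (one-sided Spearman, p = 0.006; two-sided 0.011). Under the one-sided
  convention the early-stage association is non-significant, consistent
  with the published reading; its two-sided p would be small with negative
  ρ, which the directional framing treats as absence of the hypothesised
  positive effect. Both sidednesses are always computed.

## Pipeline

One `RunConfig` (YAML) drives both phases; a single seed feeds a root
generator from which per-stage substreams derive, so identical configs
reproduce byte-identical stage artifacts (checksummed in the run manifest).
All workflow thresholds are config keys with the published values as
defaults: screen α 0.01, assessment α 0.05, GWAS threshold 5e-8, seeding
fraction 1%, progression boundaries 2/4 years (boundary durations are
intermediate — strict inequalities), staging centile 0.25, 15 PCs.

## Known limitations

- The discovery-phase counts of the motivating study (83 transcripts, 82
  modules, the specific enrichment p-values) are not reproducible without
  its undeposited microarray data; the pipeline's correctness is instead
  established by oracle equivalence, null calibration, and planted-truth
  recovery on synthetic studies.
- The scale-free fit statistic is meaningful only for networks with enough
  connectivity spread (≈ 8+ occupied bins); tiny networks fall back to the
  warning path.
- Exact tests are conservative near small margins; calibration checks use
  near-continuous regimes (gene-set-scale margins).
- The CLI is a thin wrapper; programmatic use through the library API is
  the primary interface.
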