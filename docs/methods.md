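# Methods

## Analysis model

Each 500-bp window (250-bp slide) carries a vector of per-sample
methylation scores on the reads-per-million (RPM) scale. After a coverage
filter (>= 90% of samples non-zero) and per-window normalisation, every
window is fitted with a linear mixed model:

- **Fixed effects**: age at blood draw (years, mean-centred for
  conditioning only), allelic count (0/1/2) of the enclosing LD block's
  haplotype-tagging SNP, smoking status (never/former/current,
  reference-coded), batch (reference-coded), and four leukocyte fractions
  (lymphocyte, monocyte, neutrophil, eosinophil).
- **Random effects**: a family intercept and a twin-pair intercept nested
  in family. A literal "zygosity" intercept (two levels) is inestimable as
  a variance component and would not capture twin resemblance, so pair
  within family is the working encoding; MZ and DZ pairs each get a pair
  intercept and singletons form their own pair. Longitudinal repeats share
  their individual's pair and family intercepts; no individual-level
  random effect is added beyond these.
- **Fitting**: maximum likelihood, not REML, because the inferential
  target is a fixed-effect likelihood-ratio test between nested models.
  The age test compares the full model against the same model without
  age (1 df); the genotype-by-age test compares the full model plus an
  age x count product term against the full model (1 df). Both refer the
  LRT to chi-square with 1 df; numerically negative statistics within
  1e-6 are clipped to zero. Boundary variance estimates (a component at
  0) keep the naive chi-square-1 reference, as in the standard
  anova-on-lmer workflow; this is conservative for tests on the variance
  components themselves but is the conventional choice for fixed-effect
  LRTs.

The fitter profiles out the coefficient vector and the residual variance,
leaving a bounded 2-parameter optimisation over the variance ratios
(family/residual, pair/residual; L-BFGS-B with a Nelder-Mead polish when
the family-pair ridge is flat — with two-member families the two
components are only weakly separated, which is harmless for fixed-effect
inference). For this nested structure the marginal covariance inverts in
closed form (compound-symmetry blocks within pairs, a rank-one Woodbury
correction per family), making each likelihood evaluation O(n p); a full
two-model fit takes ~10 ms at n = 350, so a 2,000-window scan with
interaction testing stays under a minute on one CPU. The implementation is
cross-checked in the tests against a dense-matrix likelihood oracle, a
closed-form GLS solution, OLS at pinned-zero variance ratios, and
statsmodels MixedLM (ML) on an identifiable design.

Normalisation is per-window z-scoring by default (matching the convention
of fitting standardised values per site); rank-based inverse-normal (Blom
offset 3/8, average ties) is available by configuration. The LRT is
invariant to any per-window affine rescaling, so the choice affects only
the scale of the reported coefficients. Zero-variance windows are flagged
and excluded. Failed or non-converged fits stay in the Bonferroni
denominator (the correction divides by all windows included in the
analysis, not all windows that converged).

**Bonferroni control**: threshold = alpha / (number of tested windows),
alpha = 0.05.

## a-DMR calling

Significant windows are sorted and merged when they overlap or are
book-ended (0-bp gap) *and* share the sign of the age coefficient; with a
250-bp slide this means one non-significant intervening window breaks a
region unless windows touch. Mixed-sign adjacency splits regions, so
every a-DMR is purely hyper- or hypomethylated. Region coordinates are
the union of the contributing window spans; the CpG count is the number
of catalogued CpG positions inside the half-open region. Merging is
order-independent (tested by permutation).

Replication refits every Bonferroni-significant discovery window in an
independent cohort with a reduced covariate set (batch fixed; family and
pair random), mirroring a replication resource without genotype, smoking
or leukocyte data, and reports three nested tiers: same direction of
effect, same direction with p < 0.05, and same direction beyond the
discovery Bonferroni level — at window level and at a-DMR level (a region
qualifies when any of its windows does). Probe-level validation marks a
region validated when a contained probe agrees in direction at p < 0.05
(nominal) or p < 1e-7 (strict), and reports regions without probe
coverage separately.

## Cell-composition controls

Peripheral blood is a meta-epigenome: cell-proportion drift with age can
masquerade as methylation ageing. Two guards:

1. **MZ blood-trait discordance EWAS.** For monozygotic pairs with
   blood-cell trait data (six traits: CD4+ T, CD8+ T, T cell, NK, CD34+,
   B), windows are residualised by OLS on smoking, the four leukocyte
   fractions, age and batch; residuals are rank-inverse-normalised per
   window; and the high-minus-low twin differences (pairs ordered by
   trait, zero-discordance pairs dropped) are tested with a one-sided
   paired t-test. A window is blood-associated when its minimum p over
   the six traits is < 0.05 (no multiplicity adjustment — deliberately
   lenient for a negative control). The a-DMR windows are then compared
   with all other windows by a continuity-corrected 2x2 chi-square: a
   non-significant result means no evidence that the called regions are
   cell-composition artefacts.
   The exact invariance of this p-value is affine (scale/shift of the raw
   scores): full monotone-transform invariance cannot hold through the
   *linear* residualisation step, only through the rank step.
2. **L-DMP overlap.** Known leukocyte-subtype differentially methylated
   positions are checked for containment in any a-DMR (half-open
   intervals); the expected count for clean calls is zero.

## Enrichment statistics

All region-set enrichment uses the non-overlapping 500-bp windows tiling
the GWAS LD blocks as background — never the whole genome, because the
block set is itself functionally enriched. A region hits a feature track
when at least a fraction f = 0.1 of its length is covered by the feature
union (intersectBed -f semantics, half-open arithmetic; the engine is
tested against a per-base counting oracle). Fold enrichment is the ratio
of hit proportions with a Pearson chi-square (no Yates correction by
default; available by flag). Chromatin-state composition reports per-state
hit fractions (a region may count toward several states, so fractions are
not a partition). DHS enrichment reports per-tissue log2 folds; a region
is blood-enriched when it hits at least 50% of the blood-tissue tracks.

Age-related-disease enrichment maps each a-DMR to its enclosing block,
blocks to their unique SNPs, and SNPs to trait associations (counted with
multiplicity at the association level, deduplicated at the SNP and block
level). The 2x2 test (a-DMR block or not x age-related or not) reports
the cross-product odds ratio (Haldane +0.5 on zero cells, flagged), the
conditional-MLE odds ratio with its exact confidence interval, and the
two-sided exact p. The a-DMR blocks are counted inside the overall
age-related fraction (union convention). The permutation null draws the
age-related fraction of blocks uniformly without replacement, counts the
overlap with the observed a-DMR blocks, and reports the add-one-smoothed
upper-tail fraction (1 + #{stat >= observed}) / (n_perm + 1), which can
never be exactly zero from finite draws; it converges to the exact
hypergeometric upper tail.

## The synthetic study

The generator emulates everything downstream of raw-read processing, from
a single seed.

- **Genome**: 3 chromosomes x 200 kb (toy scale; realistic chromosome
  sizes are a non-goal). A genetic map in 2.5-kb intervals with lognormal
  background rates (< 10 cM/Mb) and Poisson-placed hotspot intervals
  (>= 15 cM/Mb) at 40 hotspots/Mb, so each chromosome breaks into several
  LD blocks of varied size. A 150-SNP catalogue with p-values straddling
  1e-7, 15 disease classes (five flagged age-related). CpG positions with
  ~60-bp mean spacing plus dense CpG islands; blacklist intervals;
  a chromatin-state segmentation; 25 DHS tracks of which 8 are blood.
- **Cohort**: 150 families (15% singletons; 45% of pairs MZ), ages
  uniform on 19-82 with co-twins sharing their draw age; 20% of
  individuals contribute a second sample 2.2 years later; smoking
  (50/30/20%), four batches. Genotypes follow Mendelian transmission from
  simulated parents: MZ co-twins identical, DZ co-twins sharing each
  allele with probability 1/2. Leukocyte fractions are Dirichlet with an
  age trend (+0.0015 neutrophil fraction per year, mirrored in
  lymphocytes — the myeloid skew), and a fifth unmodelled component keeps
  the four modelled fractions off the simplex. The six blood-cell traits
  are lymphocyte-correlated (weights 0.1-0.7) plus an idiosyncratic
  component invisible to the four fractions — this is exactly what makes
  the MZ-discordance EWAS informative while the fraction-adjusted age
  scan stays clean.
- **Window values**: baseline = 1.0 x CpG count of the window; planted
  effects by class — age slope |0.02-0.05| RPM/year in runs of 1-3
  consecutive grid windows (210 windows), genotype beta |0.4-0.8| per
  allele (60), interaction slope |0.015-0.03| per year per allele (30),
  cell beta 0.6-1.0 per trait-SD (40); per-window smoking and batch
  shifts (SD 0.15 and 0.1); family and pair intercepts (SD 0.3 and 0.4);
  residual noise SD 0.8 scaled by 1/sqrt(depth) with a lognormal(0, 0.15)
  per-sample depth factor. Values are floored at zero. RPM is
  depth-normalised by construction, so depth cancels in the mean and
  survives only in the noise — an early design with a mean-level shared
  depth factor violated null-p uniformity (every window inherits the
  cohort's chance depth-age correlation) and was rejected on those
  grounds. Zero-inflation is concentrated in 3% of windows (30% zero
  entries), which the >= 90% coverage filter removes; planted windows
  drawing the low-coverage label are therefore excluded before testing,
  which recall metrics must account for.
- **What the generator does not emulate**: read-level sampling and the
  immunoprecipitation reaction, CpG-SNP interactions with capture
  efficiency, realistic LD structure within blocks (one tagging SNP per
  block), trait correlation structure beyond the shared lymphocyte
  component, and realistic genome/chromosome sizes. Passing tests
  therefore demonstrate the statistical machinery under the declared
  generative model, not robustness to every artefact of real MeDIP-seq
  data.

Problem sizes (about 2,000 analysis windows, ~350 samples) were chosen so
the full discovery-plus-replication study runs in a couple of minutes on
a single CPU while leaving >= 500 null and >= 200 age windows for
calibration checks; the six blood-trait "any trait at p < 0.05" fraction
is ~28% here because six one-sided tests at 5% with only partial
correlation stack up — with the near-collinear trait panels of real
cytometry data the same statistic is far smaller.

## Numerical choices and degenerate inputs

- Variance ratios bounded in [0, 100]; optimisation from (0.1, 0.1); the
  (0, 0) boundary is checked explicitly so the OLS limit is exact.
- Aliased design columns are dropped by pivoted QR before fitting.
- Monomorphic blocks make the interaction term inestimable: flagged, not
  tested.
- Windows failing the fit are flagged and reported, never silently
  dropped; they remain in the Bonferroni denominator.
- Interval arithmetic is 0-based half-open everywhere; overlap-fraction
  comparisons use a 1e-9 slack so exact boundary fractions (50/500 at
  f = 0.1) count as hits despite binary floating point.
- Empty inputs: empty catalogues and empty significant sets propagate as
  empty outputs; an empty discovery set for concordance and a zero test
  count for Bonferroni are errors.

## Known limitations

- The family and pair variance components are only weakly separated when
  most families are a single pair (as in a twin register); their sum is
  what matters for fixed-effect inference, and the reported split should
  not be over-interpreted.
- ML variance estimates are slightly biased down relative to REML, so
  coefficient standard errors are marginally anticonservative; observed
  CI coverage at study scale is ~95%.
- The chi-square reference for the LRT is asymptotic; at a few dozen
  clusters it can drift. Calibration is verified empirically at the
  default scale (type-I error within the 99% binomial band of 5%,
  KS-uniform null p-values) rather than assumed.
- a-DMR merging requires direction agreement; whether mixed-sign merges
  should ever be allowed is undecidable from summary descriptions of the
  procedure, and the split convention at least guarantees every region
  has a defined direction.
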