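# Methods

## The study design being emulated

The package models an experimental-evolution study of schooling
sociability: three replicate lines of guppies selected for high group
polarization plus three unselected control lines; ~195 nuclear families
(mother, father, three daughters, three sons) phenotyped for sociability
in 10-minute open-field trials with seven unfamiliar wild-type
conspecifics (55 cm arena, 25 Hz tracking); pooled DNA sequencing of the
mothers of the top- and bottom-quartile families within each selected
line (three replicate high/low pool pairs of seven diploid mothers); and
brain-region RNA-seq (optic tectum, telencephalon, midbrain) contrasting
fish sampled alone vs in a group.

## Trajectory phenotypes

Headings are forward displacements between consecutive frames,
normalized to unit length; frames with missing positions or zero
displacement have undefined headings. *Alignment* is the per-frame
length of the sum of the focal fish's unit heading and the unit heading
of the centroid of the tracked non-focal fish, summarized by the median
over frames; frames with fewer than six of the eight fish tracked are
excluded, and the centroid excludes the focal fish (a switch includes
it, since the group-direction convention admits both readings).
*Attraction* is the median distance to the nearest tracked conspecific.
*Activity* smooths the finite-difference velocities with a
Savitzky–Golay filter of window 13 and degree 3 — the nominal half-second
span at 25 Hz is 12 frames, but such filters need odd windows, so the
closest odd span is used — applied over contiguous tracked runs at least
one window long. *Polarization* is the per-frame length of the mean unit
heading over tracked fish. Trials with less than 70% of frame×fish cells
tracked fail QC; all thresholds are inclusive at the boundary. Medians
ignore masked frames rather than imputing.

All four metrics are checked against brute-force per-frame
re-implementations at 1e-12 on small fixtures and are invariant under
global rotation and translation (1e-9, asserted numerically).

## Quantitative genetics

**Relationship matrix.** The numerator relationship matrix A is built by
the tabular method on the full pedigree (parents processed first;
diagonal 1 + F with F half the parents' relationship). Same-sex analyses
subset the *phenotyped* individuals to one sex after building A on the
full pedigree, so relatedness through opposite-sex relatives is kept.

**Selection-regime LMM.** phenotype ~ regime * sex + generation +
group-activity covariate, with random intercepts for line, family and
stimulus-group use count, fitted by REML. Because every random term is a
plain intercept, V⁻¹ and determinants go through the Woodbury identity.
Coefficient tests use Satterthwaite degrees of freedom computed by the
delta method on the numeric REML information matrix; per-sex regime
contrasts carry a studentized-range (Tukey) adjustment. With variance
components fixed, the fit reduces exactly to GLS (tested at 1e-6).

**Animal models.** The default model separates phenotypic variance into
additive genetic variance and remaining variance, with i.i.d. random
intercepts for replicate line and stimulus-group use count and fixed
effects mirroring the LMM (regime, generation, activity; sex only when a
univariate fit spans both sexes):

    y = X beta + a + line + group_use + e,   a ~ N(0, Va * A).

A breeding-family (common-environment) intercept is available but *off
by default*, a deliberate design choice: in a same-sex nuclear-family
design every within-family pair has relatedness 1/2, so c² and h² enter
the likelihood only through 0.5·Va + V_family and are exactly
confounded; in the full design the family term is identified only
through the 195 spouse pairs and in practice mainly injects prior mass
that corrupts Va and the cross-sex covariance. Separating
common-environment from additive variance requires cross-fostering,
which this design does not have. The line and group-use terms, by
contrast, are identified through cross-family sharing and *must* stay in
the model — omitting them lets Va absorb them (their within-family share
acts exactly like a family effect). Heritability per posterior draw
divides Va by the sum of whatever components are in the model.

The bivariate full-pedigree model treats the female- and male-expressed
phenotype as two traits, each observed in one sex, with additive
covariance G = [[Va_f, c],[c, Va_m]] over the pedigree, trait-specific
fixed effects and residual variances, and shared line/group-use
intercepts. The correlation r_fm = c/(σ_af σ_am) carries an LKJ(η = 1)
prior (uniform on [−1, 1]).

**Priors.** Normal(0, 3) on fixed effects; half-Student-t(5, 0, 5) on
every random-effect standard deviation. On the unit-phenotypic-variance
scale of the simulations these are weakly informative.

**Sampler.** A partially collapsed Gibbs scheme exploits the
block-diagonal family structure of A: for the update of the genetic
(and, if enabled, family) and residual variances, the within-block
effects are integrated out analytically, giving a per-family marginal
likelihood evaluated by batched small-matrix Cholesky factorizations;
the variance block moves by adaptive random-walk Metropolis on log-SDs
(and atanh r), after which the within-block effects are redrawn from
their exact conditional. Line and group-use variances are updated with
their own intercepts collapsed (rank-one closed forms, univariate slice
sampling), then the fixed effects and all i.i.d. intercepts are redrawn jointly from
their Gaussian conditional (the joint draw removes a slow
intercept/group-mean coupling). Every update is a draw from an exact conditional
of the joint posterior. The block likelihood is verified against a dense
multivariate-normal oracle, and the full posterior was cross-checked
against an independent ensemble sampler (emcee) on one dataset — the two
agree on all marginals.

Defaults are 4 chains × 4,000 iterations (1,500 warm-up); a fit is
flagged (never silently accepted) unless split-R̂ < 1.01 and effective
sample size ≥ 1,000 for every recorded parameter (computed with arviz).
Replicated recovery experiments use 2 chains × 2,000 iterations (800
warm-up), at which posterior *medians* are stable even where the ESS
flag trips; the flags are carried in the output either way.

**Summaries.** Posterior medians and 95% highest-density intervals
(narrowest-window search; checked against an independent brute-force
scan).

## Pooled allele-frequency scan

Sync tables hold per-pool A:T:C:G:N:del read counts (1-based positions).
Sites are reduced to the two highest-count true bases summed over pools
(N and deletions never form the test pair). The filter keeps a SNP iff
every pool's A/T/C/G coverage lies in [min_coverage, max_coverage]
(defaults 25/200) and the minor allele's summed count reaches min_count
(6 merged / 18 replicate mode); it is idempotent and logs a reason per
dropped SNP. The merged scan sums high pools and low pools and applies a
two-sided Fisher exact test (vectorized hypergeometric enumeration;
verified against exhaustive enumeration on every 2×2 table with total
≤ 60); genome-wide significance uses −log₁₀ p > 8. The replicate scan is
the Cochran–Mantel–Haenszel chi-square (1 df, no continuity correction,
hypergeometric-variance convention) with the Mantel–Haenszel common odds
ratio and Benjamini–Hochberg q-values (significant iff q < 0.01). F_ST
uses the classical heterozygosity partition (h_T − h̄_S)/h_T from raw
read frequencies; the source tool's pool-size correction is deliberately
omitted. SNP→gene overlap is inclusive interval containment with a
strand-aware promoter extension (default 1,000 bp upstream — the
promoter extent is a free parameter, as no canonical definition exists).
Pool selection scores each family as the mean of the mother's and her
daughters' alignment values, z-scores within line ("normalized" admits
several readings; the z-score is the default), and takes the mothers of
the top/bottom quartile families, truncated or padded by rank to exactly
seven per pool with deterministic family-id tie-breaks.

## Expression and co-expression

RPKM = count·10⁹/(length·library size). A gene passes the low-expression
filter iff, in at least one treatment×line group, at least half of the
group's samples exceed 2 RPKM (the lenient reading of the grouping rule;
a strict all-groups variant is a switch). Size factors are
median-of-ratios with zero-containing genes excluded from the reference.
The DE test is explicitly plumbing: normalized group means, a pooled
moment estimate of NB dispersion, and a Wald test on the log₂ fold
change, with BH-FDR < 0.05 and no fold-change filter. It exists so the
clustering and intersection stages are exercisable, not to replicate a
full shrinkage-based DE estimator.

Differential co-expression keeps the permutation significance rule as
the centrepiece: the pair score is |z(r_A) − z(r_B)| with Fisher-z
Pearson correlations on log-normalized counts (a monotone surrogate for
heavier co-expression statistics; the score is pluggable), the null is
the score distribution pooled over all pairs across 1,000 random
permutations of the condition labels, and a pair is significant iff its
observed score exceeds the null's 99th percentile. The pooled (rather
than per-pair) null is the only tractable reading at 1,000 permutations
and matches the singular "distribution" of the rule. Genes constant in
either condition are skipped with a reason. Sample clustering is
agglomerative on Euclidean distances over log-normalized counts with
scipy's deterministic tie handling; trees export as Newick.

## Enrichment and concordance

Overrepresentation is a one-tail (greater) hypergeometric test per term
over an explicit background universe, Bonferroni-corrected by the number
of testable terms (those annotating ≥ 1 universe gene), significant at
adjusted p < 0.05. Concordance between two experiments is the fraction
of the test experiment's enriched terms (BP∪CC∪MF pooled) also enriched
in the reference list; the direction is a flag (with a Jaccard variant),
and an empty enriched set gives concordance 0 by convention. The
bootstrap null draws 1,000 random gene sets of the test set's size,
repeats the enrichment + concordance computation, and reports the null
mean, percentile 95% CI and the observed/mean fold increase (flagged
undefined when the mean is zero).

A consequence worth stating: with a valid Bonferroni test and
exchangeable random gene sets, at most ~5% of null sets produce any
enriched term, so bootstrap concordance distributions on synthetic
annotation are mostly zeros with a populated tail. The percentile CI is
therefore often degenerate at [0, 0], and the self-calibration check —
a random set's observed concordance falls inside the bootstrap CI ~95%
of the time — holds precisely because the ~5% of draws with enrichment
fall outside. Large null means as seen with real, deeply structured
ontologies are not reproducible from exchangeable synthetic annotation;
the generator adds per-term gene modules (co-functional groups) so the
tail is at least populated.

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical structure the analyses assume —
and nothing more:

- Pedigrees are independent nuclear families; founders are unrelated and
  non-inbred, so Mendelian sampling variance is exactly G/2. Deeper or
  inbred pedigrees are out of scope.
- Phenotypes are Gaussian on a unit-variance scale per sex with additive,
  line (0.05), family (0.02), group-use (0.02) and residual components;
  `config_for_h2` sets sex-specific residuals so the additive fraction
  equals the requested heritability exactly. The nuisance variance
  defaults are fixed a-priori choices of plausibly modest magnitude for
  a standardized lab assay, not estimates.
- The schooling simulator is a standard zonal model
  (repulsion/orientation/attraction with wrapped-normal heading noise,
  constant speed, reflective circular boundary). Only the monotone link
  between the focal fish's sociability parameters and the
  alignment/attraction metrics is claimed, and that is what is tested;
  burst-glide kinematics, bout structure and behavioural realism are
  not modelled.
- Pooled counts: neutral SNPs share one frequency within each replicate
  pair, causal SNPs split the pair by ±shift/2, and reads are
  binomial(coverage, frequency) with Poisson coverage. Equimolar pooling
  is assumed; finite-pool resampling, linkage disequilibrium and
  sequencing error are deliberately absent, which makes read sampling
  the only noise the tests must calibrate against.
- Counts are gamma-Poisson (NB) with planted log-fold-changes; DC pairs
  ride a latent factor whose loading flips sign between conditions, and
  their genes are given high expression and low dispersion so the
  planted correlation survives counting noise on the log scale.

Passing recovery tests on these data therefore demonstrates the
correctness and calibration of the estimators under the design's own
assumptions — not robustness to tracking artefacts, LD, expression
outliers or pedigree errors.

## Recovery experiments and their tolerances

`scripts/acceptance.py` (and the mirror tests) simulate ten replicate
195-family studies per setting, with generative truths set to the
reported estimates: same-sex attraction h² 0.18 (F) / 0.19 (M),
same-sex alignment h² 0.34 (F) / 0.06 (M), full-pedigree male
attraction h² 0.26 with r_fm 0.68, and alignment r_fm 0.44. Means of
posterior medians over the ten replicates recover each truth well
within the stated tolerances (internal runs deviate by at most ~0.09,
the largest case being the weakly identified alignment cross-sex
correlation); residual deviations have two known, documented sources — the family variance absorbed into Va (+2·V_family where the
design cannot separate them) and prior-geometry shrinkage of
weakly-identified positive parameters. The 95% HDIs cover the
generative r_fm in ≥ 8/10 replicates. Problem sizes (ten replicates,
2 × 2,000-iteration chains) are the package's chosen design for
replicated recovery; single analyses should use the full defaults.
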