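# Methods

This note records the statistical procedures the package implements, the
assumptions behind them, the design choices that were genuinely open, and
what the synthetic-data tests do and do not demonstrate.

## Inversion diplotype calling

**Model.**  Within the inverted interval the two lineages do not recombine,
so a biallelic SNP fixed differently on H1 and H2 ("indicator" SNP) induces
the same 3-way partition of subjects — homozygous H1 / heterozygous /
homozygous H2 — as every other indicator SNP, up to genotyping error, rare
post-divergence mutation and missing data.

**Procedure.**
1. *Seeding* (`seed_partition`): SNPs at or above a coverage threshold
   (default: full coverage; automatically relaxed to admit the ~25
   highest-coverage SNPs when none is complete) are clustered by the
   partition they induce.  Two SNPs are concordant when their class labels
   agree on shared non-missing subjects, directly or with the homozygote
   classes swapped (allele relabeling), tolerating disagreement on up to
   0.5% of compared subjects — the scale of the ~10-in-5470 contrasting
   genotypes seen in real data.  The largest cluster defines the seed
   partition by per-subject majority vote.  A candidate homozygous-minor
   group below 1% of subjects is not treated as a major category; its
   members fall through to similarity assignment (relevant when the H2
   frequency is very low).
2. *Indicator admission* (`find_indicators`): a SNP is an indicator when
   group 1 is homozygous for one allele, group 2 heterozygous and group 3
   counter-homozygous, ignoring missing data, with at most `max_discordant`
   (default 10) discordant subjects in total.  The group-3 allele is
   recorded as H2-tagging; with an empty group 3 it is inferred from the
   heterozygotes.
3. *Assignment* (`assign_subjects`): every subject is scored against the
   three orientation-implied consensus genotype vectors over the indicator
   SNPs (matches / non-missing comparisons) and assigned by argmax.  Ties
   and all-missing subjects are left UNASSIGNED (excluded from regression)
   rather than guessed.  After assignment the larger homozygous group is
   labelled H1_H1 — H2 is assumed minor, which is true in every surveyed
   population; at H2 frequency exactly 0.5 the two lineage names become
   exchangeable and only the partition is identifiable.
4. *Representative SNP* (`pick_representative`): the indicator SNP with
   maximal call rate, ties broken by smallest genomic position.  The H2
   allele frequency estimate is (2·n_H2H2 + n_H1H2) / (2·n_assigned).

The multiple-alignment visualisation step used historically for this kind of
analysis is replaced by the direct algorithmic grouping above;
`export_concat_fasta` still writes the concatenated diploid-base sequences
(two characters per SNP, `NN` for missing) for optional visual inspection in
an alignment viewer.

## Genotype and subject filters

Marker QC removes, in order (each SNP charged to the first rule it fails,
which makes the exclusion report deterministic): indel-coded markers,
monomorphic SNPs, SNPs genotyped in < 75% of subjects, and SNPs with minor
allele frequency ≤ 1% (computed on non-missing alleles — standard practice;
the alternative of counting missing calls is not defensible).  Region slices
use closed 1-based GRCh37 intervals.  The completed-family filter keeps
women aged ≥ 45 and men aged ≥ 55 (sex coded 1 = female, 2 = male); subjects
with missing sex or age are dropped with a logged warning.  Subject counts
are logged at every stage rather than assuming any particular cohort
composition.

## Zero-inflated negative-binomial regression

**Recoding.**  `recode_nonevents` maps counts ≤ 3 to zero and leaves larger
counts unshifted, so the response support is {0} ∪ {4, 5, ...}.  The
likelihood is evaluated literally on this recoded response (no shift); the
count component is a full NB2 even though values 1–3 cannot occur.  This is
the straightforward reading of the recode-as-non-event design, and its main
consequence — that the count parameters are informed almost entirely by the
observed large families — is shared by the original analysis.

**Weights.**  One-year age bins; raw weight 1/n_bin per subject, rescaled so
the weights sum to N (equivalently N/(B·n_bin) with B distinct bins).  Bins
are pooled across the sexes.  Scaling all weights by a constant multiplies
the log-likelihood but leaves estimates unchanged (tested).

**Likelihood and score.**  Written in log space with numerically exact
large-theta behaviour: the Gamma-function ratio log Γ(y+θ) − log Γ(θ) is the
rising-factorial sum Σ_{i<y} log(θ+i), log(θ/(θ+μ)) is −softplus(η−ρ) with
ρ = log θ, and θ/(θ+μ) = expit(ρ−η).  Without these forms, catastrophic
cancellation near the Poisson boundary (θ ~ 10^6, as the real data demands)
corrupts both the optimizer and the observed information.

**Fitting.**  Starts: weighted Poisson IRLS for the count part, weighted
logistic IRLS of 1{y=0} for the zero part, log θ = 0.  Optimization:
L-BFGS-B with the analytic score on column-scaled designs (raw age makes the
problem needlessly ill-conditioned), log θ box-bounded at ±20 (θ ≈ 4.85·10^8;
at the bound the likelihood is flat and θ is reported as boundary), followed
by up to 25 damped Newton steps using a score-Jacobian Hessian — interaction
designs leave L-BFGS crawling near the optimum and the Newton polish
finishes them.  Convergence: optimizer success or score max-norm < 10^-3;
the fitted log-likelihood is verified not to fall below the starting value.

**Inference.**  Standard errors from the inverse observed information
(central-difference Jacobian of the analytic score); z = estimate/SE,
two-sided normal p.  Term tests are Wald chi-squares W = b'V⁻¹b on the
count-component coefficient block of each term (df = block size), matching
the convention in which a single-df term's chi-square equals its z².  A
boundary θ excludes the log θ row from the information inverse and reports
the overdispersion p as 1 with a note.  `bonferroni` applies p < α/m with
m = 7 by default (the representative SNP plus six surrogates; negative
controls are excluded from m).

**Interaction pruning.**  The full genotype × age × sex factorial is fitted
in both components; if every interaction coefficient has Wald p ≥ 0.05 the
model is refitted with main effects only (main effects are retained even
when non-significant).  If the full model cannot be formed or does not
converge, the main-effects model is used with a warning.  Note that with ~16
interaction coefficients this any-coefficient rule keeps a null interaction
model with appreciable probability; it is retained as the study's stated
rule rather than replaced by a joint block test.

**Reference level.**  Genotype dummies are taken against the
smaller-homozygote (H2-homozygote) class, heterozygote dummy first — the
convention of the published coefficient table, where CT and TT enter against
a CC baseline.  With only one homozygote class present it becomes the
reference; a representative SNP lacking all three classes yields status
"model not formed" in the pipeline rather than an error.

## Two-locus LD and surrogate selection

Haplotype frequencies for a SNP pair are estimated from the 3×3 unphased
genotype table by EM under random union of gametes, initialized at linkage
equilibrium; only the double-heterozygote cell is phase-ambiguous and is
split by its posterior cis/trans probability each iteration.  Convergence:
max frequency change < 10^-8 (cap 1000 iterations); degenerate zero cells
stay at the boundary — no pseudocounts, which would bias small-sample LOD.
The EM likelihood is asserted non-decreasing every step.

From the fitted frequencies: D = p_AB − p_A·p_B; D′ = D/D_max with D_max =
min(p_A·p_b, p_a·p_B) for D > 0 and min(p_A·p_B, p_a·p_b) otherwise;
r² = D²/(p_A p_a p_B p_b); LOD = log10 multinomial likelihood ratio of the
fitted frequencies against independence at the same allele margins (clipped
at 0 against rounding).  Monomorphic loci raise an error naming the locus.

Surrogate selection: candidates on the target's chromosome within a closed
±50 000 bp window, kept when the Hardy-Weinberg chi-square p ≥ 0.05 (1-df
test with expectations from allele frequencies; monomorphic samples return
p = 1 by convention) and LOD ≥ 3, ranked by LOD descending with absolute
distance as tie-break; the top two are returned and may lie on the same side
of the target.  Distances are signed, negative = upstream.

## Synthetic cohort generator

`SimConfig` defaults define the study conditions: 5470 subjects; H2
haplotype frequency 0.159 with diplotypes drawn under Hardy-Weinberg; 22
indicator SNPs carrying distinct alleles on the two lineages plus 77 noise
SNPs with random allele frequencies (uniform 0.05–0.5) independent of the
inversion; positions uniform in 17:43,793,582–44,776,837; per-call
missingness 2% and genotype-error rate 0.1% (an error replaces the call with
a uniformly random other genotype of that SNP, mirroring the observed
contrasting-genotype scale); ages uniform integers 45–90; equal sexes.

Children counts: with probability π_i = logistic(3.9066 − 0.0274·age) a
subject is a structural non-event and draws NCI from the observed 0–3
composition (proportions 1713:1051:1641:747); otherwise NCI ~ NB(μ_i, θ)
with log μ_i = 1.9866 − 0.5084·1{het} − 0.5574·1{H1-hom} (H2-homozygote
reference, as in the published coefficient table) and θ = 10^6 (effectively
Poisson).  Count draws ≤ 3 land in the non-event band on recoding, so the
descriptive tables see realistic 0–3 counts while the regression sees the
mixture.  Sex has no simulated effect.  All randomness flows from a single
seeded generator; fixtures are byte-identical per seed.

`simulate_zinb_response` draws directly from the ZINB likelihood itself
(structural zeros plus an untruncated NB).  Estimator-validation runs (bias,
coverage, type-I error) use this exact-model generator, because calibration
statements are only interpretable when the data-generating process coincides
with the fitted model; the recoding mixture above is deliberately *not* a
ZINB on the recoded support, and fits to it carry a small truncation-induced
bias that the end-to-end tests bound at 3 SE instead.  Calibration runs use
an H2 frequency of 0.3 — chosen a priori so every genotype class is large
enough (dozens of count-part events) for Wald asymptotics to be meaningful
at the simulated sizes — with 100 runs of n = 5000 for bias/coverage and
1000 runs of n = 2000 for the type-I rate, sizes picked to keep the suite
fast while leaving the binomial acceptance bands comfortably wide.

**What the generator does not emulate:** linkage structure beyond the
inversion block (noise SNPs are independent), duplication subtypes
(H1D/H2D), population stratification, relatedness, secular cohort effects
beyond the linear age term, and questionnaire artefacts.  Passing tests
therefore demonstrate correctness of the algorithms under the stated model,
not robustness to those real-data complications.

## Degenerate inputs and tie-breaking

- Unordered genotypes: "T C" and "C T" normalize to the same call; missing
  is "0 0" in PED, "00" internally, "NN" in FASTA.
- Seeding with no full-coverage SNP raises a typed error with the relaxation
  exposed as an option; the orchestrator relaxes automatically and logs it.
- Assignment ties → UNASSIGNED, logged, excluded from regression.
- Representative-SNP ties → smallest position.
- Surrogate LOD ties → smallest absolute distance.
- Empty genotype classes make the descriptive contrasts an error, not NaN.
- The "3-dp display" contrast variant rounds each group mean to 3 decimals
  before subtracting, reproducing arithmetic quoted from rounded tables;
  full-precision contrasts are always reported alongside.

## Problem sizes used by the checks

The acceptance script simulates one cohort of 5470 subjects for the caller
metrics, one exact-model dataset of 50 000 subjects for coefficient
recovery, and one LD pair of 10 000 subjects; the test suite uses cohorts of
120–2000 subjects, 100 × n = 5000 recovery fits, 1000 × n = 2000 null fits
and 50 EM-versus-grid-oracle tables.  These sizes are the package's choices
for a fast, reproducible suite; all scale linearly if larger runs are
wanted.

## Known limitations

- The caller assumes exactly two non-recombining lineages; duplicated or
  recombinant subtypes would appear as discordant subjects and, beyond the
  tolerance, as excluded SNPs.
- The gap-support recode (no shift) is one of two defensible readings of
  the non-event design; the alternative (shifting counts) is not
  implemented.
- Weights are computed in pooled (not sex-stratified) age bins.
- The LD surrogate stage operates on whatever genotype panel it is given;
  no external reference panels are fetched or parsed.
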