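# inv17q

Association analysis between the chromosome 17q21.31 H1/H2 inversion and
numbers of children, built as a tested, reusable pipeline with a synthetic
cohort generator so every stage runs without access to the original data.

## The scientific problem

The ~900 kb inversion at 17q21.31 segregates as two deeply diverged,
non-recombining haplotype lineages, H1 and H2 (H2 is the minor lineage in
Europeans and has been linked to higher fertility in Icelandic data).  Because
recombination is suppressed, SNPs inside the inverted interval split unrelated
subjects into three clean classes — homozygous H1, heterozygous, homozygous
H2 — so the diplotype can be called from unphased genotypes alone.  The
question is whether the diplotype is associated with the number of children
per individual (NCI) reported by questionnaire.

The package is aimed at statistical geneticists who want to reproduce or
extend this analysis: it reads PLINK text PED/MAP genotypes, applies the
marker and completed-family filters, calls diplotypes, and fits the
association model.

## The model

Family sizes of 0–3 children are recoded to zero as **non-events**, so the
count component models only larger-than-average families.  The recoded count
y_i follows a weighted zero-inflated negative binomial:

```
P(y_i = 0)     = pi_i + (1 - pi_i) * f_NB(0; mu_i, theta)
P(y_i = k > 0) = (1 - pi_i) * f_NB(k; mu_i, theta)

log mu_i   = x_i' beta        (count part, NB2 with log link)
logit pi_i = z_i' gamma       (zero part, binomial with logit link)
```

with genotype dummies (heterozygote and H1-homozygote against the
H2-homozygote reference), age and sex in both parts, per-subject weights
proportional to the inverse size of each one-year age bin (rescaled to sum to
N), and dispersion theta (variance mu + mu^2/theta; theta → ∞ is Poisson).
The likelihood, analytic score and quasi-Newton fit are implemented from
first principles in `inv17q.zinb`; genotype association is judged by a Wald
chi-square on the count-part genotype block (type-II style), interactions are
pruned when none is significant, overdispersion is checked via the Wald
p-value of log(theta), and a Bonferroni menu of 7 SNPs (the inversion
representative plus six surrogates) sets the adjusted level 0.05/7.

Supporting machinery: EM haplotype-frequency estimation with D, D′, r² and
LOD for surrogate-SNP selection within ±50 kb (`inv17q.ld`), a
Hardy-Weinberg chi-square filter, a random negative-control sampler, and the
diplotype caller (`inv17q.caller`).

## Worked example

The analysis is organised as numbered drivers over the library:

```bash
python analysis/01_simulate_cohort.py    # cohort -> scratch/cohort/
python analysis/02_call_inversion.py
python analysis/03_descriptives.py
python analysis/04_fit_zinb.py
python analysis/05_ld_surrogates.py
python analysis/06_negative_controls.py
```

`02_call_inversion.py` prints, for the default simulated cohort (5470
subjects, H2 frequency 0.159, 2% missingness, 0.1% genotype errors):

```
group sizes: {'H1_H1': 3868, 'H1_H2': 1467, 'H2_H2': 135, 'UNASSIGNED': 0}
indicator SNPs: 21; representative: ind010
H2 allele frequency: 0.1588 (study estimate 0.159)
accuracy vs planted truth: 100.00%
```

i.e. the caller recovers every planted diplotype and the H2 allele frequency
matches the generating value.  `03_descriptives.py` recomputes the published
rs12373123 cross-tabulation (the C allele tags H2):

```
mean NCI CC 2.4419 (n=43)   CT 2.3466 (n=554)   TT 2.3145 (n=1418)
H2 allele prevalence: 15.9%
recessive contrast (3dp display): +0.118
dominant contrast  (3dp display): +0.038
```

H2 homozygotes average ~0.12 more children than carriers of at least one H1
haplotype — the recessive-model contrast.  `04_fit_zinb.py` fits the weighted
ZINB on the simulated cohort and prints the coefficient table, the term
tests and the Bonferroni decision for the SNP term.

The same pipeline is scriptable via the `inv17q` CLI (`simulate`,
`call-inversion`, `descriptives`, `fit`, `surrogates`, `controls`,
`run-all`) and as one call, `inv17q.pipeline.run_full_analysis`.

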