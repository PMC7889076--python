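# Methods

## Study-effect estimation

Each dataset contributes one standardized effect per gene and covariate.
For the binary covariate (newborn sex, 1 = male) the effect is Hedges'
small-sample-corrected standardized mean difference,

    g = J (x̄₁ − x̄₀) / s_pooled,   J = 1 − 3/(4·df − 1),   df = n₁ + n₀ − 2,
    var(g) = (n₁+n₀)/(n₁n₀) + g²/(2(n₁+n₀)).

For the continuous/ordinal covariates (gestational age in weeks,
birthweight in grams, pre-pregnancy BMI category 0–3 treated as numeric)
the effect is the Fisher-transformed Pearson correlation, z = atanh(r) with
variance 1/(n−3). Both are dimensionless and inverse-variance combinable,
which is what the combination step requires. How the original analyses
handled continuous covariates inside a two-class meta-analysis framework is
not recoverable; these estimators are the documented substitute. Datasets
need at least four samples and a non-degenerate covariate, otherwise they
are rejected ("insufficient data").

Raw (non-normalized) matrices are quantile normalized across samples — tied
values receive the mean of the reference quantiles they span — then
log2(x+1) transformed. Probes mapping to one gene collapse to the max-mean
row, a convention that is stable under normalization.

## Random-effects combination and calibration

Per gene and covariate, effects from the k datasets containing both are
combined with DerSimonian–Laird moments: fixed weights w = 1/v, Q = Σw(e −
ê_FE)², τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)), random weights w* = 1/(v +
τ²), μ = Σw*e/Σw*, se = (Σw*)^(−1/2), z = μ/se. When Q ≤ k−1 this reduces
exactly to the fixed-effect combination; single-study genes pass through
with τ² = 0 and a flag rather than being dropped, since the pooled score
tolerates missing components.

The closed-form two-sided normal p-value of z is reported (`p_normal`), but
it is *not* used for significance by default. Under a homogeneous null the
truncation τ² ≥ 0 inflates the estimated standard error in roughly half of
all genes, so the marginal distribution of z has SD ≈ 0.92 rather than 1
and the normal reference is conservative (empirical type-I ≈ 0.033 at
α = 0.05 in this pipeline's default geometry). Gene-level significance is
therefore calibrated against a permutation null: each dataset's covariate
labels are permuted (expression fixed), the full combination is recomputed,
and the |z| values from 50 permutations × all genes form a pooled null.
This is the convention of permutation-based microarray meta-analysis and
restores type-I error to its nominal level (measured 0.047 at 8000 null
gene-tests). BH q-values are computed over the tested genes.

## Pooled risk score

z_pooled = ((z_Male + z_PPBMI) − (z_GA + z_BW)) / 4. The risk orientation
negates GA and BW because longer gestation and higher birthweight are
protective. A gene missing from a component analysis contributes z = 0 and
the denominator stays 4; this deliberately shrinks sparsely measured genes
toward zero rather than letting two noisy components masquerade as a
four-way consensus. Representativeness diagnostics report the Spearman
correlation (average-rank ties) of each risk-oriented component with the
pooled score and with the mean of the other components.

## Pre-ranked enrichment

Genes are sorted by the metric (descending, gene-id tie-break for
reproducibility). For a set of size k in a list of N, member genes increment
a running sum by |m|^w / Σ_set |m|^w (w = 1 by default) and non-members
decrement it by 1/(N−k); the enrichment score is the signed extremum, with
exact peak/trough ties resolving positive. Significance uses gene-label
permutation — membership redrawn uniformly, metric fixed — which is the
appropriate null when only a pre-ranked statistic exists; the null is
shared across sets of equal effective size. NES divides ES by the mean
|null ES| of matching sign and the one-sided p-value uses the matching-sign
null with +1 smoothing, so p ≥ 1/(nperm+1). Sets are filtered to an
effective size of 10–500 by default (no filter is dictated by the source
analyses; this is standard practice). BH q-values are computed across
retained sets.

## Replication in the RNA-seq cohort

Risk factors are counted with strict inequalities: GA < 37 weeks,
birthweight < 3000 g, PP BMI > 30, male (the alternative preset swaps PP
BMI for cesarean delivery); boundary values contribute zero. Genes with
median count < 10 are dropped; "median sum scaling" is interpreted as
rescaling each library to the median library size, which enters the models
as an offset log(total/median total). Per gene, a negative-binomial
log-linear model of counts on the risk count is fit by joint maximum
likelihood (NB2); if the MLE diverges, a Poisson fit supplies a
method-of-moments dispersion and the model is refit as an NB GLM with that
dispersion fixed. No dispersion shrinkage or information sharing across
genes is attempted. The Wald z of the slope is positive when expression
rises with risk.

RS = z_pooled × z_RNAseq on the gene intersection, passing at RS > 3 by
default. A rank-based variant (normal scores of each z vector before the
product) is exposed because the source analyses are ambiguous about whether
ranks were substituted; the plain product is the definition of record. The
cutoff sweep reports passing-gene counts and median source p-values per
cutoff. The signature eigenvalue standardizes each passing gene across
subjects, extracts the first principal component of the subject × gene
matrix, and orients it so the mean loading of low-risk genes (z_pooled < 0)
is positive. Compositional cell-type abundances use the centered log-ratio
transform with an additive pseudo-count of half the smallest nonzero part
(configurable) before Pearson correlation with Bonferroni adjustment.

## Outcome models

Protein concentrations are log10 transformed and standardized to an
internal z-score (sample SD, non-missing values). Binary outcomes use
logistic regression with Wald CIs, continuous outcomes linear regression
with t-based CIs, per 1 SD of the protein z. The adjustment sets are:
model 1 — GA, birthweight-for-GA-and-sex z, delivery mode, child sex, child
race/ethnicity; model 2 — maternal PP BMI, race/ethnicity, education,
atopy, pregnancy antibiotic use, smoking; model 3 — the union minus
maternal race/ethnicity. Reference levels are White (race), never-smoker,
vaginal delivery. Analyses are complete-case per model; subjects with
missing outcomes are excluded.

LMG relative importance computes each predictor block's average R²
increment over all orders of entry via exact subset enumeration, grouped
dummies entering as one block; shares are nonnegative and sum to the
full-model R². Logistic relative importance is the drop in McFadden
pseudo-R² (1 − ll/ll₀) when one block is removed from the full model.
Subset analyses refit the univariate model inside each stratum of a
categorical covariate (strata under 10 usable subjects skipped with a
warning) and flag heterogeneity when two strata have disjoint 95% CIs — a
deliberately coarse screen, not a formal interaction test. Questionnaire
-derived outcomes use three-valued logic: current asthma requires a
diagnosis plus recent medication or wheeze, the comparison group requires
the absence of all three, and anything else (including through missing
answers) is missing.

## Synthetic-data generator

The generator is the test bed, and its defaults are the study conditions:
eleven datasets of sizes 37, 20, 64, 47, 48, 38, 38, 128, 16, 23, 146
(605 samples) with the covariate-availability pattern of a realistic
multi-study compendium (sex in 6 datasets / 386 samples, GA in 7 / 386, BW
in 5 / 235, PP BMI in 4 / 164); 2000 genes of which 50 carry signal at a
standardized effect of 0.6 per risk factor with sign ±1; unit expression
noise; a 30-subject RNA-seq cohort with NB dispersion 0.1, 2-fold library
variation, and slopes ±0.6 per risk factor for signal genes; a 358-subject
outcome cohort with a generator odds ratio of 0.5 per SD of the
outcome-linked protein and an FEV1/FVC shift of 1.15 points per SD.

Covariate marginals are chosen as typical obstetric ranges, not estimates
of any real cohort: sex Bernoulli(0.5); GA ~ Normal(39.2, 1.8) weeks
truncated to [24, 42] (the truncation pulls the realized mean to ≈ 39.0);
birthweight ~ Normal(3400, 500) g with correlation 0.5 to GA; BMI ~
Normal(26.5, 5.5) mapped to the ordinal 0–3 category by the 18.5/25/30
cutpoints. All four covariates always drive expression; a dataset's
availability mask only hides them from the metadata, mirroring the fact
that availability is a reporting property. The two simulated serum proteins
are log-normal with correlation ≈ 0.2; the outcome-linked one loads weakly
on GA, sex and delivery mode so that adjusted and unadjusted estimates
differ, and the null one has no outcome effect. An optional effect-modifier
hook plants an interaction for the subset-analysis tests.

What the generator does **not** emulate: platform-specific probe intensity
distributions, batch effects beyond per-dataset baseline shifts, correlated
gene-gene expression modules, dispersion trends in counts, cohort
attrition, or measurement error in the proteins. Passing tests therefore
demonstrate that the statistical machinery is correct and calibrated under
the declared model, not that the biological findings would reproduce on
real cohorts.

## Numerical choices and problem sizes

Determinism: every generator draws from seed-derived independent streams,
so identical seeds give byte-identical TSV outputs; permutation p-values
and enrichment nulls take explicit seeds. Degenerate inputs error loudly
(constant matrices, zero-variance proteins, zero-total libraries, singular
designs — the offending term is named). The enrichment peak/trough
tie-break carries a 1e-12 slack so exact mathematical ties resolve
positively regardless of floating-point summation order. The acceptance
script uses the default problem sizes above (2000 genes, 11 datasets, 30
RNA-seq subjects, 358-subject cohorts, 250 Monte-Carlo replicates, 1000
enrichment permutations, 50 meta-analysis permutations), which keep a full
from-scratch run under a minute on one CPU while leaving Monte-Carlo error
well inside the tolerances the tests assert.

## Known limitations

- The DL estimator itself (not just its p-values) is noisy at small k; no
  Hartung–Knapp or REML alternatives are provided.
- NB dispersion is estimated per gene without shrinkage; with 30 subjects
  the Wald z is only asymptotically normal (the null suite verifies the
  approximation is adequate at this size).
- The heterogeneity flag in subset analyses is a disjoint-CI screen with no
  multiplicity control.
- Real-data coefficient tables are not bit-reproducible even in principle,
  since the original dummy codings and covariate transformations are not
  fully printed; the pipeline validates recovery of generator parameters
  instead.
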