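# Methods

## Score construction

The risk score is a Cox proportional-hazards linear predictor built in two
stages on a training split (ceil of 2/3 of subjects; the remainder is the
internal test set).

*Screen.* Each candidate biomarker is fitted in its own Cox model together
with age, sex and a dummy-coded study indicator. Biomarkers and age are
z-standardized with training means and population (ddof = 0) standard
deviations; sex is a 0/1 indicator left unscaled. Candidates with a Wald
p-value below 0.1 pass. The printed univariate model form repeats one
coefficient symbol for sex and study; we fit distinct coefficients, with one
dummy per non-reference study.

*Selection.* Greedy forward selection over the screened set minimizes
BIC = −2·log PL + k·log(d), where d is the number of events — the effective
sample size of a partial likelihood — and k counts every fitted coefficient
including the study dummies (a constant offset across candidate models, so
it never changes a comparison). Selection stops when no addition lowers the
BIC; ties between equally scoring candidates break alphabetically for
determinism. Age and sex are eligible candidates (a `force` option pins
them); the study label is an adjustment covariate only and never enters the
transferable score, since a biobank has no trial-study structure. The
`non-urine` variant simply drops urine-flagged biomarkers from the candidate
set before screening.

Ties in event times use the Efron approximation (lifelines' default). The
solver's relative log-likelihood stopping rule leaves roughly 1e-7 relative
error in the coefficients; wherever coefficients are reported or serialized
(the screen and the final refit) we restart the Newton iteration once from
the optimum, which squares that residual away. Selection-loop fits skip the
polish — BIC differences at that scale never change a selection decision.

Scoring a cohort uses the training centers and scales verbatim:
R = Σ β̂_j (y_j − m_j)/s_j, with no baseline-hazard term, so R transfers to
any cohort carrying the same measurements. Subjects missing any selected
variable are dropped from scoring with a logged count; there is no
imputation.

## Validation

Harrell's C is computed by exact pair enumeration (vectorized in row
chunks). A pair is comparable when the earlier observed time belongs to a
subject with an event; two events tied in time are non-comparable; an event
tied with a censored subject counts the censored one as the longer survivor;
tied scores contribute 1/2. Subset rules before scoring: baseline
eGFR strictly greater than the cutoff (default 25 ml/min/1.73 m², excluding
late-stage disease in which progression cannot be observed), optionally a
baseline diabetes diagnosis; missing filter values exclude the subject with
a logged count.

## Association and post-processing

The per-variant scan is an ordinary least-squares regression of the score on
allele count, vectorized by residualizing phenotype and genotypes on the
covariates; it is a desk-scale stand-in for a mixed-model association
platform and assumes unrelated subjects with no population structure.
Monomorphic variants are emitted with p = 1 and an exclusion flag and never
enter downstream estimates.

Loci chain genome-wide-significant variants (p < 5·10⁻⁸) whose consecutive
positions lie within 100 kb, then add ±100 kb flanks clipped at position 1.
Because a gap in (100, 200] kb separates two chains whose flanked intervals
still overlap, overlapping flanked loci are merged; loci on a chromosome are
therefore pairwise disjoint and every significant variant belongs to exactly
one locus. The chaining direction is symmetric.

The inflation factor uses the variants outside all significant loci:
λ = (empirical 0.99 quantile of χ² = Z²) / χ²₁(0.99) = q̂/6.6349. The 0.99
χ² quantile corresponds to the 1st percentile of p-values; the quantile is
configurable. When λ > 1, every variant's Z is divided by λ (the `gc_mode`
switch offers the classic √λ convention instead) and p-values are recomputed
from the normal tail; loci are then redefined on the adjusted p-values. When
λ ≤ 1 nothing is adjusted.

## Burden testing

A mask selects qualifying variants by consequence class and annotation MAF
ceiling, or singletons only (exactly one allele observed in the cohort;
class restrictions still apply). Carriers hold at least one qualifying
allele; homozygous carriers count toward carrier status but not toward the
heterozygous-carrier count that the support filter inspects (a literal
reading of the filter; both counts are reported). The test is OLS of the
score on carrier status plus covariates — appropriate for a continuous
phenotype at desk scale. Hits require p < α/(n_genes · n_phenotypes) with a
caller-declared denominator (17,857 × 1 reproduces the conventional
2.8·10⁻⁶ exome-wide threshold), strictly more than 20 heterozygous carriers,
and a mask that is neither singletons-only nor capped at MAF ≤ 0.001.
Removed hits carry machine-readable filter reasons; no result is silently
dropped. Carrier support is counted per mask, not per gene.

## Novelty

Colocalization is the standard single-causal-variant enumeration over
Wakefield log approximate Bayes factors, lABF = ½[log(V/(V+W)) +
Z²·W/(V+W)] with V = se², combined into the five hypotheses with priors
p1 = p2 = 10⁻⁴, p12 = 10⁻⁵ and prior effect variance W = 0.15² (quantitative
traits; all configurable). W is in squared effect units, so the posterior is
exactly invariant to a common unit rescaling of β, se and √W. Variants are
matched across traits by chromosome, position and alleles, with flipped
alleles harmonized by reversing the second trait's effect sign. Hypothesis
sums use log-sum-exp throughout; the distinct-causal term is the full cross
product minus the shared diagonal, evaluated as a stable log1p difference.

A locus is colocalization-tested only against score components with at least
one genome-wide-significant variant inside it; it is labeled *known* if any
such test gives PP4 strictly above 0.5, otherwise *novel* (vacuously novel
when no component is significant). A failed colocalization is recorded in
the decision trace and treated as non-colocalizing. Gene mapping accepts the
unique maximum-probability gene per locus when its externally supplied
causal probability exceeds 0.5; ties at the maximum are ambiguous and left
unmapped. Burden novelty is a set difference against each component's own
filtered hit list, with the matching components recorded for every
discarded gene.

## Synthetic data

The generator emulates the study design, not any real cohort. Biomarkers are
exchangeably correlated unit-variance Gaussians (default ρ = 0.3), optionally
mean-shifted per cohort — the external cohort shifts each risk-increasing
biomarker downward by 0.5 SD, reproducing a population with more low-risk
subjects — and optionally reported on a raw affine scale so the
unit-alignment step is exercised. Event times come from a Weibull baseline
(shape 1.5, scale 5) by inverse transform on the proportional-hazards
survival function; the baseline family is a modelling choice made for
closed-form sampling. Censoring is independent exponential with its rate
calibrated by bisection so the expected censored fraction matches the target
(default 0.7, a trial-like event rate of ~30%); the Kaplan–Meier event
fraction lands within a few percentage points of the target at n ≥ 2000.

Common-variant genotypes are Hardy–Weinberg at uniform-drawn MAFs with block
LD from a within-block latent Gaussian copula over two haplotypes (default
block size 10, latent ρ = 0.6); blocks are laid over chromosomes 1–22 with
10 kb spacing inside a block and 1 Mb between blocks, which makes locus
chaining non-trivial without emulating a real LD map. Planted causal
variants either perturb one score-component biomarker before the score is
computed (component-driven: the effect reaches the score through the
biomarker, and genotype–biomarker correlation is nonzero only for these) or
add directly to the composite score (score-only). Rare coding variants
(binomial HWE, no LD) are assigned to genes with consequence classes drawn
from {LOF, missense-pathogenic, missense-benign, other} at 0.2/0.3/0.3/0.2;
a planted gene effect shifts the scores of carriers of any deleterious
variant in that gene. Causal-gene probabilities for locus mapping are
fabricated from the planted truth (a synthetic surrogate for an external
gene-prioritization tool): the lead-variant gene of a truly causal locus
gets 0.75–0.99, decoys stay below 0.5.

Every generator is deterministic given seed and configuration; the pipeline
fans a single global seed into per-stage child seeds through
`numpy.random.SeedSequence`.

What passing the synthetic experiments does *not* show: robustness to
realistic LD structure, population stratification or relatedness,
measurement error and unit mismatches beyond affine rescaling, informative
censoring, competing risks, or miscalibrated external pathogenicity and
gene-probability inputs. The association models are exact for the generative
model used here and approximations for real biobank data.

## Default problem sizes

The shipped study conditions (also used by `scripts/acceptance.py`) are a
2,400-subject trial and biobank, 5 biomarkers (3 active), 1,500 common
variants with two component-driven and two score-only causal variants
(effects 0.6 on the biomarker and 0.45 on the score, MAFs ≥ 0.1), 40 genes
with one planted burden gene (carrier shift 1.2, rare MAFs 1.5–6·10⁻³ so
carrier counts clear the support filter), and the exome-wide Bonferroni
denominator 17,857. Calibration summaries use 50,000 null variants for the
inflation factor and n = 4,000 with 15 candidates for selection recovery.
These sizes give planted-signal Z-scores around 7–10, comfortably separated
from the null while keeping a full run around a minute on one CPU.

## Known limitations

- The burden test is plain OLS; no Firth/saddlepoint correction, no
  variance-component (SKAT-style) alternative.
- Single-causal-variant colocalization only; allelic heterogeneity within a
  locus violates its core assumption.
- The λ estimator is a tail-quantile ratio; very sparse panels make the
  0.99 quantile noisy (at least 100 outside-locus variants are required).
- Heritability and genetic-correlation estimation, imputation, exome QC and
  pathogenicity prediction are out of scope; annotations and gene
  probabilities are consumed as inputs.
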