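# backtrans

Back-translation of clinical risk scores into biobank genetics.

Clinical trials collect deep phenotypes but almost never genotypes; biobanks
collect genomes but shallow, cross-sectional phenotypes. `backtrans`
implements the bridge: derive a parsimonious Cox proportional-hazards risk
score from a trial-like cohort, validate its discrimination externally,
compute it for every subject of a genotyped cohort, and treat the score as a
quantitative GWAS/burden phenotype whose association results are then
post-processed into a ranked list of *novel* candidate loci and genes — ones
not explained by any single score-component biomarker.

It is written for statistical geneticists and biostatisticians who want a
tested, end-to-end desk-scale implementation of this workflow, including a
synthetic-data generator with recorded ground truth for calibration and
recovery experiments.

## The model

**Score construction.** For subject *i* with standardized biomarker values
*y*<sub>ij</sub>, each candidate *j* is screened in a univariate Cox model

λ<sub>j</sub>(t | Y<sub>j</sub>) = λ<sub>0,j</sub>(t) · exp(β<sub>1,j</sub> y<sub>ij</sub> + β₂ a<sub>i</sub> + β₃ s<sub>i</sub> + **β₄**ᵀ D<sub>i</sub>),

with age *a*, sex *s* and dummy-coded study *D* as adjustments; candidates
with Wald p < 0.1 enter greedy forward selection minimizing
BIC = −2·log PL + k·log(d) (d = events). The final score is the transferable
linear predictor

R<sub>i</sub> = Σ<sub>j∈S\*</sub> β̂<sub>j</sub> · (y<sub>ij</sub> − m<sub>j</sub>)/s<sub>j</sub>,

with training centers/scales (m, s) frozen into the serialized model.

**Validation.** Harrell's concordance index over comparable pairs under
right censoring, after subset rules (baseline eGFR > 25 ml/min/1.73 m²,
optionally diabetes at baseline).

**Post-processing.** Per-variant OLS of R on allele counts; genome-wide
significant variants (p < 5·10⁻⁸) chained into loci at ≤ 100 kb gaps with
±100 kb flanks; inflation factor λ = (0.99 empirical quantile of χ² outside
loci) / 6.6349, and if λ > 1, z* = z/λ for all variants with loci redefined
on the adjusted p-values. Gene-level burden tests collapse rare deleterious
variants per mask; hits require p < α/(genes × phenotypes) (2.8·10⁻⁶ at the
exome-wide denominator), more than 20 heterozygous carriers, and a
non-ultra-rare mask. Novelty: a locus is *known* if it colocalizes
(single-causal-variant ABF enumeration, PP4 > 0.5) with any score-component
biomarker significant in the locus; novel loci are mapped to the unique gene
with causal probability > 0.5; burden hits are novel if absent from every
component's own hit list.

## Worked example

```python
import backtrans as bt

sim = bt.SimulationConfig(
    n_subjects=2400, n_biomarkers=5, n_variants=1500, ld_block_size=10,
    ld_rho=0.5, maf_range=(0.1, 0.5), n_genes=40, n_rare_variants=320,
    rare_maf_range=(1.5e-3, 6e-3), seed=3)
truth = bt.SimulationTruth(
    true_coefficients={"bm0": 0.8, "bm1": -0.6, "bm2": 0.5},
    causal_variants=[
        bt.CausalVariant("1_1000000_G_A", 0.6, "component-driven", "bm0"),
        bt.CausalVariant("3_1000000_G_A", 0.45, "score-only"),
    ],
    gene_effects={"GENE7": 1.2}, seed=3)
report = bt.run_all(bt.RunConfig(simulation=sim, truth=truth, seed=3,
                                 n_genes_tested=17857), outdir="run")
print(report.to_json())
```

prints (abridged):

```json
{
  "selected_variables": ["bm0", "bm1", "bm2"],
  "c_index_internal": 0.7558,
  "c_index_external": 0.7498,
  "lambda_inflation": 1.0221,
  "n_loci_adjusted": 2,
  "n_loci_known": 1,
  "n_loci_novel": 1,
  "n_loci_mapped": 1,
  "n_burden_novel": 1,
  "burden_novel_genes": ["GENE7"]
}
```

Forward selection recovers the three active biomarkers; the fitted score
discriminates with C ≈ 0.75 internally and externally. The component-driven
variant surfaces as a locus that colocalizes with `bm0`'s own GWAS (known);
the score-only variant yields a locus with no significant component signal
(novel) and is mapped to its candidate gene; the planted burden gene
survives the carrier-count and mask filters and is absent from every
component's hit list, so it appears in `burden_novel_genes`.

The same stages are available as a CLI:

```sh
backtrans simulate --seed 1 --n-subjects 2000 --out cohort.tsv
backtrans build-score --cohort cohort.tsv --variant non-urine --out model.json
backtrans validate --model model.json --cohort external.tsv --egfr-min 25
backtrans run-all --outdir run/
```

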