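"""End-to-end orchestration of the four framework stages on synthetic data:

1. build a Cox risk score on a trial-like cohort (train/test split, screen,
   BIC forward selection);
2. validate it internally and on a shifted external cohort (subset rules,
   concordance);
3. transfer it to a genotyped biobank-like cohort and run the variant
   association plus summary-statistic post-processing (loci, inflation,
   adjustment, locus redefinition) and the rare-variant burden scan;
4. novelty filtering: component colocalization for loci, hit intersection
   for burden genes, causal-gene prioritization.

A single global seed fans out deterministically to per-stage child seeds, so
identical configurations produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import split_train_test
from .simulate import (CausalVariant, SimulationConfig, SimulationTruth,
                       fabricate_gene_probabilities, gen_cohort, simulate_biobank)
from .score import RiskScoreModel
from .validate import validate_score
from .gwas import (adjust_zscores, define_loci, inflation_factor, loci_table,
                   redefine_loci_after_adjustment, run_variant_association,
                   write_sumstats)
from .burden import (DEFAULT_MASKS, filter_hits, gene_summary, results_table,
                     run_burden_scan)
from .novelty import (novelty_filter_burden, novelty_filter_snp,
                      priorities_table, prioritize_genes)


@dataclass
class RunConfig:
    """All knobs of a full synthetic run, serializable to/from YAML."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    truth: SimulationTruth = field(default_factory=SimulationTruth)
    seed: int = 0
    variant: str = "urine"
    train_fraction: float = 2.0 / 3.0
    screen_threshold: float = 0.1
    n_biobank: int | None = None
    external_shift: dict[str, float] = field(default_factory=dict)
    egfr_min: float = 25.0
    sig_threshold: float = 5e-8
    flank_bp: int = 100_000
    chain_gap_bp: int = 100_000
    lambda_quantile: float = 0.99
    gc_mode: str = "z_over_lambda"
    burden_alpha: float = 0.05
    n_genes_tested: int | None = None
    n_phenotypes_tested: int = 1
    min_het_carriers: int = 20
    coloc_priors: dict[str, float] = field(default_factory=lambda: {"p1": 1e-4, "p2": 1e-4, "p12": 1e-5})
    coloc_w: float = 0.15 ** 2
    h4_threshold: float = 0.5
    gene_prob_threshold: float = 0.5

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["simulation"] = SimulationConfig(**payload.get("simulation", {}))
        truth = payload.get("truth", {})
        truth["causal_variants"] = [CausalVariant(**cv)
                                    for cv in truth.get("causal_variants", [])]
        payload["truth"] = SimulationTruth(**truth)
        return cls(**payload)


@dataclass
class RunReport:
    """Machine-readable run outcome: filter counts at every partition plus
    the headline metrics."""

    seed: int
    variant: str
    version: str
    n_train: int
    n_test: int
    n_biobank: int
    selected_variables: list[str]
    c_index_internal: float
    c_index_external: float
    c_index_external_diabetic: float
    lambda_inflation: float
    lambda_applied: bool
    n_loci_initial: int
    n_loci_adjusted: int
    n_loci_novel: int
    n_loci_known: int
    n_loci_mapped: int
    n_burden_tests: int
    n_burden_hits: int
    n_burden_hits_filtered_out: int
    n_burden_novel: int
    burden_novel_genes: list[str]

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _child_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def run_all(config: RunConfig, outdir=None) -> RunReport:
    """Execute the four stages in order; artifacts are written under
    ``outdir`` when given, and a stage manifest is kept current so a failing
    stage leaves the completed-stage outputs intact."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    def done(stage: str) -> None:
        manifest.append(stage)
        if out is not None:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    sim = config.simulation
    s_trial, s_split, s_ext, s_bio, s_genes = (
        int(ss.generate_state(1)[0] % (2 ** 31)) for ss in _child_seeds(config.seed, 5))

    # ---- stage 1: score construction on the trial-like cohort
    trial = gen_cohort(sim, config.truth, label="trial", seed=s_trial)
    train, test = split_train_test(trial, config.train_fraction, seed=s_split)
    results = RiskScoreModel(train, variant=config.variant,
                             screen_threshold=config.screen_threshold).fit()
    if out is not None:
        results.to_json(out / "model.json")
        train.to_tsv(out / "train.tsv")
        test.to_tsv(out / "test.tsv")
    done("build-score")

    # ---- stage 2: internal + external validation
    internal = validate_score(results, test, label="internal-test")
    shift = config.external_shift or {
        b: -0.5 * np.sign(config.truth.true_coefficients.get(b, 0.0))
        for b in sim.biomarker_names()
    }
    external = gen_cohort(sim, config.truth, label="external", seed=s_ext, shift=shift)
    ext_all = validate_score(results, external, egfr_min=config.egfr_min)
    ext_dm = validate_score(results, external, egfr_min=config.egfr_min,
                            require_diabetes=True)
    if out is not None:
        pd.DataFrame([r.to_dict() for r in (internal, ext_all, ext_dm)]).to_csv(
            out / "validation.tsv", sep="\t", index=False)
    done("validate")

    # ---- stage 3: transfer + genetic association + post-processing
    bio_sim = (sim if config.n_biobank is None
               else dataclasses.replace(sim, n_subjects=config.n_biobank))
    biobank = simulate_biobank(bio_sim, config.truth, results, seed=s_bio)
    covs = biobank.cohort.data.loc[biobank.scores.index, ["age", "sex"]].to_numpy(float)
    sumstats = run_variant_association(biobank.scores.to_numpy(),
                                       biobank.genotypes, covariates=covs)
    loci0 = define_loci(sumstats, config.sig_threshold, config.flank_bp,
                        config.chain_gap_bp)
    adj = inflation_factor(sumstats, loci0, quantile=config.lambda_quantile)
    adjusted = adjust_zscores(sumstats, adj, gc_mode=config.gc_mode)
    loci = redefine_loci_after_adjustment(
        adjusted, sig_threshold=config.sig_threshold, flank_bp=config.flank_bp,
        chain_gap_bp=config.chain_gap_bp)

    masks = DEFAULT_MASKS
    n_genes_declared = config.n_genes_tested or bio_sim.n_genes
    burden_raw = run_burden_scan(biobank.rare_genotypes, biobank.annotations,
                                 biobank.scores.to_numpy(), masks=masks,
                                 covariates=covs)
    burden_res = filter_hits(burden_raw, n_genes=n_genes_declared,
                             n_phenotypes=config.n_phenotypes_tested,
                             alpha=config.burden_alpha,
                             min_het_carriers=config.min_het_carriers, masks=masks)
    if out is not None:
        write_sumstats(adjusted, out / "sumstats.tsv")
        loci_table(loci).to_csv(out / "loci.tsv", sep="\t", index=False)
        results_table(burden_res).to_csv(out / "burden.tsv", sep="\t", index=False)
    done("associate")

    # ---- stage 4: novelty filtering and gene prioritization
    score_biomarkers = [v for v in results.selected
                        if v in biobank.cohort.biomarkers]
    component_stats = {
        b: run_variant_association(
            biobank.cohort.data.loc[biobank.scores.index, b].to_numpy(float),
            biobank.genotypes, covariates=covs)
        for b in score_biomarkers
    }
    partition = novelty_filter_snp(loci, adjusted, component_stats,
                                   h4_threshold=config.h4_threshold,
                                   sig_threshold=config.sig_threshold,
                                   priors=config.coloc_priors, w=config.coloc_w)
    gene_probs = fabricate_gene_probabilities(partition.novel, config.truth,
                                              biobank.genotypes, seed=s_genes)
    priorities = prioritize_genes(partition.novel, gene_probs,
                                  threshold=config.gene_prob_threshold)

    score_hit_genes = set(gene_summary(burden_res)["gene"])
    component_hits = {}
    for b in score_biomarkers:
        raw = run_burden_scan(biobank.rare_genotypes, biobank.annotations,
                              biobank.cohort.data.loc[biobank.scores.index, b]
                              .to_numpy(float), masks=masks, covariates=covs)
        comp_res = filter_hits(raw, n_genes=n_genes_declared,
                               n_phenotypes=config.n_phenotypes_tested,
                               alpha=config.burden_alpha,
                               min_het_carriers=config.min_het_carriers,
                               masks=masks)
        component_hits[b] = set(gene_summary(comp_res)["gene"])
    novel_genes, discarded = novelty_filter_burden(score_hit_genes, component_hits)
    if out is not None:
        partition.trace.to_csv(out / "coloc_trace.tsv", sep="\t", index=False)
        priorities_table(priorities).to_csv(out / "gene_priorities.tsv",
                                            sep="\t", index=False)
    done("novelty")

    n_hits = sum(r.hit for r in burden_res)
    n_filtered_out = sum((not r.hit) and r.p < config.burden_alpha
                         / (n_genes_declared * config.n_phenotypes_tested)
                         and "not_significant" not in r.filter_reasons
                         for r in burden_res)
    report = RunReport(
        seed=config.seed, variant=config.variant, version=__version__,
        n_train=len(train), n_test=len(test), n_biobank=len(biobank.cohort),
        selected_variables=results.selected,
        c_index_internal=internal.c_index,
        c_index_external=ext_all.c_index,
        c_index_external_diabetic=ext_dm.c_index,
        lambda_inflation=adj.lambda_, lambda_applied=adj.applied,
        n_loci_initial=len(loci0), n_loci_adjusted=len(loci),
        n_loci_novel=len(partition.novel), n_loci_known=len(partition.known),
        n_loci_mapped=sum(p.mapped for p in priorities),
        n_burden_tests=len(burden_res), n_burden_hits=n_hits,
        n_burden_hits_filtered_out=n_filtered_out,
        n_burden_novel=len(novel_genes), burden_novel_genes=novel_genes,
    )
    if out is not None:
        report.to_json(out / "report.json")
    done("report")
    return report
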