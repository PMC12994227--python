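"""Synthetic multi-cohort survival data, genotypes and annotations.

The generator emulates the study design the package targets: a trial-like
cohort with correlated baseline biomarkers and a right-censored survival
outcome driven by a sparse linear predictor; an external validation cohort
whose covariate distribution is shifted toward lower risk; and a biobank-like
cohort with Hardy–Weinberg genotypes in LD blocks, where some planted causal
variants act on the composite risk score through a component biomarker
("component-driven") and others act on the score only ("score-only").  Every
generated dataset is paired with a :class:`SimulationTruth` recording the
generative parameters so that recovery tests can compare estimates against
the truth.

Survival times are drawn from a Weibull baseline by inverse transform on the
proportional-hazards survival function; censoring is independent exponential
with its rate calibrated by bisection to a target censoring fraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import CohortTable

CONSEQUENCE_CLASSES = ("LOF", "missense-pathogenic", "missense-benign", "other")
#: classes treated as deleterious when planting gene-level burden effects
DELETERIOUS_CLASSES = ("LOF", "missense-pathogenic")


@dataclass
class CausalVariant:
    """A planted causal variant and its mechanism.

    ``mechanism`` is ``"component-driven"`` (the allele perturbs one score
    component biomarker, so its effect reaches the score through that
    biomarker) or ``"score-only"`` (the allele perturbs the composite score
    directly, leaving every component biomarker untouched).
    """

    variant_id: str
    effect: float
    mechanism: str
    biomarker: str | None = None

    def __post_init__(self) -> None:
        if self.mechanism not in ("component-driven", "score-only"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism == "component-driven" and not self.biomarker:
            raise ValueError("component-driven variants must name a biomarker")


@dataclass
class SimulationTruth:
    """Ground truth of a simulation run (log-hazard coefficients per SD,
    causal variants with mechanism tags, per-gene burden effects)."""

    true_coefficients: dict[str, float] = field(default_factory=dict)
    causal_variants: list[CausalVariant] = field(default_factory=list)
    gene_effects: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [cv.variant_id for cv in self.causal_variants]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate causal variant ids")

    def to_json(self, path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["causal_variants"] = [CausalVariant(**cv) for cv in payload["causal_variants"]]
        return cls(**payload)


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults give a desk-scale study.

    Biomarkers are exchangeably correlated unit-variance Gaussians; the
    baseline hazard is Weibull(shape, scale); ``censoring_target`` is the
    fraction of subjects censored before their event.  Genetics: ``n_variants``
    common variants in LD blocks of ``ld_block_size`` with within-block latent
    correlation ``ld_rho``, plus ``n_rare_variants`` rare coding variants
    distributed over ``n_genes`` genes for burden testing.
    """

    n_subjects: int = 2000
    n_biomarkers: int = 10
    biomarker_rho: float = 0.3
    weibull_shape: float = 1.5
    weibull_scale: float = 5.0
    censoring_target: float = 0.7
    n_studies: int = 2
    n_variants: int = 4000
    ld_block_size: int = 10
    ld_rho: float = 0.6
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_genes: int = 50
    n_rare_variants: int = 400
    rare_maf_range: tuple[float, float] = (2e-4, 5e-3)
    seed: int = 0

    def __post_init__(self) -> None:
        self.maf_range = tuple(self.maf_range)
        self.rare_maf_range = tuple(self.rare_maf_range)
        for name in ("n_subjects", "n_biomarkers", "n_studies", "n_variants",
                     "ld_block_size", "n_genes", "n_rare_variants"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.censoring_target < 1:
            raise ValueError("censoring_target must lie in [0, 1)")
        for lo, hi in (self.maf_range, self.rare_maf_range):
            if not (0 < lo <= hi <= 0.5):
                raise ValueError("MAF range must satisfy 0 < low <= high <= 0.5")
        if not -1 / max(self.n_biomarkers - 1, 1) < self.biomarker_rho < 1:
            raise ValueError("biomarker correlation outside the PSD range")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.ld_block_size > self.n_variants:
            raise ValueError("LD block size exceeds variant count")

    def biomarker_names(self) -> list[str]:
        return [f"bm{j}" for j in range(self.n_biomarkers)]


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _exchangeable_chol(p: int, rho: float) -> np.ndarray:
    corr = np.full((p, p), rho)
    np.fill_diagonal(corr, 1.0)
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as err:
        raise ValueError("biomarker correlation spec is not positive semidefinite") from err


def calibrate_censoring_rate(event_times: np.ndarray, target: float) -> float:
    """Exponential censoring rate such that the expected censored fraction,
    given the drawn event times, matches ``target`` (bisection)."""
    if target <= 0:
        return 0.0

    def frac(rate: float) -> float:
        return float(np.mean(-np.expm1(-rate * event_times)))

    hi = 1.0 / max(np.median(event_times), 1e-12)
    while frac(hi) < target:
        hi *= 2
        if hi > 1e12:
            raise ValueError(f"censoring target {target} unreachable; achieved {frac(hi):.3f}")
    return float(optimize.brentq(lambda r: frac(r) - target, 0.0, hi, xtol=1e-12))


def gen_cohort(
    config: SimulationConfig,
    truth: SimulationTruth,
    label: str = "trial",
    seed=None,
    shift: np.ndarray | dict[str, float] | None = None,
    unit_scale: float = 1.0,
    unit_offset: float = 0.0,
    biomarker_values: np.ndarray | None = None,
) -> CohortTable:
    """Draw a cohort from the proportional-hazards generative model.

    ``shift`` adds per-biomarker mean offsets (the external-cohort covariate
    shift); ``unit_scale``/``unit_offset`` report the biomarkers on a raw
    affine scale so the unit-alignment step is exercised.  ``biomarker_values``
    injects a pre-built (already shifted/perturbed) biomarker matrix and is
    used when genetic effects must reach the outcome through a biomarker.
    """
    rng = _as_rng(config.seed if seed is None else seed)
    n, names = config.n_subjects, config.biomarker_names()
    unknown = [b for b in truth.true_coefficients if b not in names]
    if unknown:
        raise ValueError(f"truth names biomarkers the config does not generate: {unknown}")

    if biomarker_values is None:
        chol = _exchangeable_chol(config.n_biomarkers, config.biomarker_rho)
        y = rng.standard_normal((n, config.n_biomarkers)) @ chol.T
        if shift is not None:
            if isinstance(shift, dict):
                vec = np.array([shift.get(b, 0.0) for b in names])
            else:
                vec = np.asarray(shift, dtype=float)
            y = y + vec
    else:
        y = np.asarray(biomarker_values, dtype=float)
        if y.shape != (n, config.n_biomarkers):
            raise ValueError("biomarker_values shape mismatch")

    beta = np.array([truth.true_coefficients.get(b, 0.0) for b in names])
    lp = y @ beta
    # inverse-transform sampling: S(t|x) = exp(-(t/scale)^shape * e^lp)
    u = rng.uniform(size=n)
    t_event = config.weibull_scale * (-np.log(u) * np.exp(-lp)) ** (1.0 / config.weibull_shape)

    if config.censoring_target > 0:
        rate = calibrate_censoring_rate(t_event, config.censoring_target)
        t_cens = rng.exponential(1.0 / rate, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)
    time = np.maximum(time, 1e-9)

    data = pd.DataFrame({
        "id": [f"{label}-{i}" for i in range(n)],
        "age": rng.normal(65.0, 8.0, size=n).round(1),
        "sex": rng.integers(0, 2, size=n),
        "study": rng.integers(1, config.n_studies + 1, size=n).astype(str),
        "time": time,
        "event": event,
        # auxiliary clinical columns used only by validation subset rules
        "egfr": np.clip(rng.normal(55.0, 20.0, size=n), 5.0, None).round(1),
        "diabetes": rng.integers(0, 2, size=n),
    })
    unit = "standardized" if (unit_scale == 1.0 and unit_offset == 0.0) else "raw"
    for j, b in enumerate(names):
        data[b] = unit_scale * y[:, j] + unit_offset
    return CohortTable(
        data=data,
        biomarkers=names,
        units={b: unit for b in names},
        urine={b: b.endswith("_u") for b in names},
        label=label,
    )


@dataclass
class GenotypeMatrix:
    """Subjects × variants allele-count matrix with per-variant metadata."""

    matrix: np.ndarray  # int8, values {0,1,2}
    variant_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ea: np.ndarray
    oa: np.ndarray
    maf: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.variant_ids):
            raise ValueError("variant metadata length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_variants(self) -> int:
        return self.matrix.shape[1]

    def index_of(self, variant_id: str) -> int:
        return self.variant_ids.index(variant_id)

    def to_tsv(self, path) -> None:
        meta = pd.DataFrame({
            "ID": self.variant_ids, "CHR": self.chrom, "POS": self.pos,
            "EA": self.ea, "OA": self.oa, "MAF": self.maf,
        })
        geno = pd.DataFrame(self.matrix.T, columns=[f"s{i}" for i in range(self.n_subjects)])
        pd.concat([meta, geno], axis=1).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t")
        meta_cols = ["ID", "CHR", "POS", "EA", "OA", "MAF"]
        geno = df.drop(columns=meta_cols).to_numpy(dtype=np.int8).T
        return cls(
            matrix=geno, variant_ids=df["ID"].tolist(),
            chrom=df["CHR"].to_numpy(str), pos=df["POS"].to_numpy(np.int64),
            ea=df["EA"].to_numpy(str), oa=df["OA"].to_numpy(str),
            maf=df["MAF"].to_numpy(float),
        )


def _hwe_block_genotypes(rng, n_subjects, mafs, rho) -> np.ndarray:
    """HWE genotypes with block LD: two latent-Gaussian haplotypes per subject,
    exchangeable correlation ``rho`` across the block's variants."""
    m = len(mafs)
    chol = _exchangeable_chol(m, rho) if m > 1 else np.ones((1, 1))
    thresh = stats.norm.ppf(mafs)
    g = np.zeros((n_subjects, m), dtype=np.int8)
    for _ in range(2):  # two haplotypes -> HWE marginally
        z = rng.standard_normal((n_subjects, m)) @ chol.T
        g += (z < thresh).astype(np.int8)
    return g


def gen_genetics(config: SimulationConfig, seed=None, n_subjects: int | None = None) -> GenotypeMatrix:
    """Common-variant genotypes: HWE at uniform-drawn MAFs, block LD via a
    within-block latent Gaussian copula, blocks laid out over chromosomes
    1..22 with 10 kb spacing inside a block and 1 Mb between blocks."""
    rng = _as_rng(config.seed if seed is None else seed)
    n = config.n_subjects if n_subjects is None else n_subjects
    p, bs = config.n_variants, config.ld_block_size
    n_blocks = -(-p // bs)
    mafs = rng.uniform(*config.maf_range, size=p)

    cols, chroms, poss = [], [], []
    block_of_chrom: dict[int, int] = {}
    for b in range(n_blocks):
        lo, hi = b * bs, min((b + 1) * bs, p)
        cols.append(_hwe_block_genotypes(rng, n, mafs[lo:hi], config.ld_rho))
        chrom = (b % 22) + 1
        k = block_of_chrom.get(chrom, 0)
        block_of_chrom[chrom] = k + 1
        start = 1_000_000 + k * 1_000_000
        chroms.extend([str(chrom)] * (hi - lo))
        poss.extend(start + 10_000 * j for j in range(hi - lo))
    matrix = np.concatenate(cols, axis=1)
    ids = [f"{c}_{q}_G_A" for c, q in zip(chroms, poss)]
    return GenotypeMatrix(
        matrix=matrix, variant_ids=ids,
        chrom=np.array(chroms), pos=np.array(poss, dtype=np.int64),
        ea=np.array(["A"] * p), oa=np.array(["G"] * p), maf=mafs,
    )


def gen_rare_variants(
    config: SimulationConfig, seed=None, n_subjects: int | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Rare coding variants (binomial HWE, no LD) assigned to genes with a
    consequence class; the annotation MAF is the empirical allele frequency so
    singleton masks behave consistently."""
    rng = _as_rng(config.seed if seed is None else seed)
    n = config.n_subjects if n_subjects is None else n_subjects
    p = config.n_rare_variants
    mafs = rng.uniform(*config.rare_maf_range, size=p)
    matrix = rng.binomial(2, mafs, size=(n, p)).astype(np.int8)
    genes = np.array([f"GENE{v % config.n_genes}" for v in range(p)])
    classes = rng.choice(CONSEQUENCE_CLASSES, size=p, p=[0.2, 0.3, 0.3, 0.2])
    chrom = np.array(["23"] * p)  # exonic toy contig, outside the GWAS panel
    pos = np.arange(1, p + 1, dtype=np.int64) * 1000
    ids = [f"rare{v}" for v in range(p)]
    emp_maf = matrix.mean(axis=0) / 2.0
    ann = pd.DataFrame({
        "variant_id": ids, "chrom": chrom, "pos": pos, "gene": genes,
        "class": classes, "maf": emp_maf,
    })
    geno = GenotypeMatrix(
        matrix=matrix, variant_ids=ids, chrom=chrom, pos=pos,
        ea=np.array(["T"] * p), oa=np.array(["C"] * p), maf=emp_maf,
    )
    return geno, ann


@dataclass
class BiobankData:
    """A simulated genotyped cohort with its score phenotype and rare-variant
    annotations; ``scores`` is the GWAS/burden phenotype (model-derived score
    plus any planted score-only and gene-burden effects)."""

    cohort: CohortTable
    scores: pd.Series
    genotypes: GenotypeMatrix
    rare_genotypes: GenotypeMatrix
    annotations: pd.DataFrame
    truth: SimulationTruth


def simulate_biobank(
    config: SimulationConfig,
    truth: SimulationTruth,
    score_results,
    seed=None,
    shift: np.ndarray | dict[str, float] | None = None,
    label: str = "biobank",
) -> BiobankData:
    """Generate a biobank cohort and apply planted genetic effects.

    Component-driven causal variants perturb their target biomarker *before*
    the risk score is computed (the effect flows into the score through the
    biomarker, and genotype–biomarker correlation is nonzero only for these
    variants); score-only variants and gene burden effects are added to the
    composite score afterwards and leave every biomarker untouched.
    """
    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    rng_bio, rng_geno, rng_rare, rng_cohort = (np.random.default_rng(s) for s in ss.spawn(4))
    n, names = config.n_subjects, config.biomarker_names()

    geno = gen_genetics(config, seed=rng_geno, n_subjects=n)
    rare, ann = gen_rare_variants(config, seed=rng_rare, n_subjects=n)

    chol = _exchangeable_chol(config.n_biomarkers, config.biomarker_rho)
    y = rng_bio.standard_normal((n, config.n_biomarkers)) @ chol.T
    if shift is not None:
        vec = (np.array([shift.get(b, 0.0) for b in names])
               if isinstance(shift, dict) else np.asarray(shift, dtype=float))
        y = y + vec
    for cv in truth.causal_variants:
        if cv.mechanism == "component-driven":
            g = geno.matrix[:, geno.index_of(cv.variant_id)].astype(float)
            y[:, names.index(cv.biomarker)] += cv.effect * (g - g.mean())

    cohort = gen_cohort(config, truth, label=label, seed=rng_cohort, biomarker_values=y)
    scores = score_results.predict(cohort)

    extra = np.zeros(n)
    for cv in truth.causal_variants:
        if cv.mechanism == "score-only":
            g = geno.matrix[:, geno.index_of(cv.variant_id)].astype(float)
            extra += cv.effect * (g - g.mean())
    for gene, effect in truth.gene_effects.items():
        qual = ann.index[(ann["gene"] == gene) & ann["class"].isin(DELETERIOUS_CLASSES)].to_numpy()
        if qual.size == 0:
            raise ValueError(f"gene {gene} has no deleterious variants to carry its effect")
        carrier = (rare.matrix[:, qual].sum(axis=1) > 0).astype(float)
        extra += effect * carrier

    scores = scores + pd.Series(extra, index=scores.index)
    return BiobankData(cohort=cohort, scores=scores, genotypes=geno,
                       rare_genotypes=rare, annotations=ann, truth=truth)


def fabricate_gene_probabilities(
    loci, truth: SimulationTruth, genotypes: GenotypeMatrix, seed=0
) -> pd.DataFrame:
    """Stand-in causal-gene probability table (synthetic surrogate for an
    external gene-prioritization tool): each locus gets a handful of candidate
    genes; when the locus lead variant is a planted causal variant, the gene
    named after it receives a high probability, decoys stay below 0.5."""
    rng = _as_rng(seed)
    causal_ids = {cv.variant_id for cv in truth.causal_variants}
    rows = []
    for locus in loci:
        lead = locus.lead_id
        genes = [f"LG_{locus.chrom}_{locus.start}_{k}" for k in range(2)]
        probs = rng.uniform(0.05, 0.45, size=2)
        if lead in causal_ids:
            genes.append(f"CAUSAL_{lead}")
            probs = np.append(probs, rng.uniform(0.75, 0.99))
        for g, p in zip(genes, probs):
            rows.append({"locus_id": locus.locus_id, "gene": g, "probability": float(p)})
    return pd.DataFrame(rows, columns=["locus_id", "gene", "probability"])
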