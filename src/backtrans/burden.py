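"""Gene-level collapsing (burden) tests of rare coding variation against the
continuous risk score, with mask taxonomy and post-hoc hit filters.

A *mask* selects qualifying variants per gene by consequence class and allele
frequency (optionally singletons only).  Subjects carrying at least one
qualifying allele form the carrier group; the burden test is an OLS of the
score on carrier status plus covariates.  Hits are declared by Bonferroni
correction over a user-declared genes × phenotypes denominator, then pruned:
hits supported by ≤ 20 heterozygous carriers and hits obtained only under
ultra-rare masks (MAF ceiling ≤ 0.001 or singletons-only) are removed, with
the removal reason recorded — no result is ever silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gwas import _residualize

#: masks whose MAF ceiling is at or below this are "exceedingly rare" and
#: cannot support a reportable hit on their own
ULTRA_RARE_MAF = 0.001


@dataclass(frozen=True)
class MaskDefinition:
    """Qualifying-variant rule set for collapsing."""

    name: str
    classes: tuple[str, ...]
    maf_ceiling: float = 0.01
    singleton_only: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.maf_ceiling <= 0.5:
            raise ValueError("MAF ceiling must lie in (0, 0.5]")

    @property
    def ultra_rare(self) -> bool:
        return self.singleton_only or self.maf_ceiling <= ULTRA_RARE_MAF


DEFAULT_MASKS = (
    MaskDefinition("lof", ("LOF",), maf_ceiling=0.01),
    MaskDefinition("lof_pathogenic", ("LOF", "missense-pathogenic"), maf_ceiling=0.01),
    MaskDefinition("lof_pathogenic_rare", ("LOF", "missense-pathogenic"), maf_ceiling=0.001),
    MaskDefinition("singleton_lof", ("LOF",), singleton_only=True),
)


@dataclass
class CollapseResult:
    """Per-gene carrier vector under one mask, with carrier bookkeeping."""

    gene: str
    mask: str
    carrier: np.ndarray  # 0/1 per subject
    n_carriers: int
    n_het_carriers: int
    n_variants: int


def collapse_gene(rare_genotypes, annotations: pd.DataFrame, gene: str,
                  mask: MaskDefinition) -> CollapseResult:
    """Indicator of carrying ≥ 1 qualifying allele in ``gene`` under ``mask``.

    Homozygous carriers count toward carrier status, but the heterozygous
    carrier count — the quantity the downstream support filter inspects —
    only counts carriers whose qualifying genotypes are all heterozygous.
    """
    if gene not in set(annotations["gene"]):
        raise KeyError(f"gene {gene!r} absent from annotations")
    ann = annotations.loc[annotations["gene"] == gene]
    sel = ann["class"].isin(mask.classes)
    if mask.singleton_only:  # MAF ceiling irrelevant: exactly one allele observed
        ac = np.array([int(rare_genotypes.matrix[:, rare_genotypes.index_of(v)].sum())
                       for v in ann["variant_id"]])
        sel &= pd.Series(ac == 1, index=ann.index)
    else:
        sel &= ann["maf"] <= mask.maf_ceiling
    idx = [rare_genotypes.index_of(v) for v in ann.loc[sel, "variant_id"]]
    if not idx:
        n = rare_genotypes.n_subjects
        return CollapseResult(gene, mask.name, np.zeros(n, dtype=np.int8), 0, 0, 0)
    sub = rare_genotypes.matrix[:, idx]
    carrier = (sub.sum(axis=1) > 0).astype(np.int8)
    het_only = carrier.astype(bool) & (sub.max(axis=1) == 1)
    return CollapseResult(gene, mask.name, carrier,
                          int(carrier.sum()), int(het_only.sum()), len(idx))


@dataclass
class BurdenResult:
    """One gene × mask association record."""

    gene: str
    mask: str
    n_carriers: int
    n_het_carriers: int
    n_variants: int
    beta: float
    se: float
    p: float
    p_corrected: float | None = None
    hit: bool = False
    filter_reasons: list[str] = field(default_factory=list)


def burden_test(collapse: CollapseResult, scores, covariates=None) -> BurdenResult:
    """OLS of the score on carrier status (plus covariates), two-sided p.

    A degenerate carrier vector (all carriers or none) yields p = 1 with the
    reason flagged.
    """
    y = np.asarray(scores, dtype=float)
    c = collapse.carrier.astype(float)
    if c.min() == c.max():
        return BurdenResult(collapse.gene, collapse.mask, collapse.n_carriers,
                            collapse.n_het_carriers, collapse.n_variants,
                            beta=0.0, se=np.nan, p=1.0,
                            filter_reasons=["degenerate_carrier_vector"])
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    n_cov = 1 + (0 if cov is None else cov.shape[1])
    yr = _residualize(y, cov)
    cr = _residualize(c, cov)
    sxx = float((cr ** 2).sum())
    beta = float(cr @ yr / sxx)
    df = len(y) - n_cov - 1
    rss = float((yr ** 2).sum()) - beta ** 2 * sxx
    se = float(np.sqrt(max(rss, 0.0) / max(df, 1) / sxx))
    z = beta / se if se > 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    return BurdenResult(collapse.gene, collapse.mask, collapse.n_carriers,
                        collapse.n_het_carriers, collapse.n_variants,
                        beta=beta, se=se, p=max(p, 1e-320))


def run_burden_scan(rare_genotypes, annotations, scores, masks=DEFAULT_MASKS,
                    covariates=None) -> list[BurdenResult]:
    """All gene × mask burden tests over the annotated gene set."""
    out = []
    for gene in sorted(annotations["gene"].unique()):
        for mask in masks:
            out.append(burden_test(
                collapse_gene(rare_genotypes, annotations, gene, mask),
                scores, covariates))
    return out


def filter_hits(
    results,
    n_genes: int,
    n_phenotypes: int = 1,
    alpha: float = 0.05,
    min_het_carriers: int = 20,
    masks=DEFAULT_MASKS,
) -> list[BurdenResult]:
    """Declare and prune hits; every result is returned annotated.

    Hit iff p < alpha/(n_genes · n_phenotypes).  Declared hits are then
    removed when supported by ≤ ``min_het_carriers`` heterozygous carriers,
    or when obtained under an ultra-rare mask (singletons-only or MAF ceiling
    ≤ 0.001).  The Bonferroni denominator is declared by the caller since it
    depends on the full testing design.
    """
    if n_genes <= 0 or n_phenotypes <= 0:
        raise ValueError("Bonferroni denominator terms must be positive")
    m = n_genes * n_phenotypes
    threshold = alpha / m
    mask_by_name = {mk.name: mk for mk in masks}
    out = []
    for r in results:
        reasons = list(r.filter_reasons)
        p_corr = min(1.0, r.p * m)
        is_hit = r.p < threshold and not reasons
        if is_hit and r.n_het_carriers <= min_het_carriers:
            reasons.append(f"het_carriers<={min_het_carriers}")
            is_hit = False
        mk = mask_by_name.get(r.mask)
        if is_hit and mk is not None and mk.ultra_rare:
            reasons.append("ultra_rare_mask")
            is_hit = False
        if not is_hit and not reasons:
            reasons.append("not_significant")
        out.append(BurdenResult(r.gene, r.mask, r.n_carriers, r.n_het_carriers,
                                r.n_variants, r.beta, r.se, r.p,
                                p_corrected=p_corr, hit=is_hit,
                                filter_reasons=reasons))
    return out


def gene_summary(filtered) -> pd.DataFrame:
    """Per-gene summary over surviving masks: the smallest corrected p among
    this gene's hits (genes without any hit are omitted)."""
    rows = [r for r in filtered if r.hit]
    if not rows:
        return pd.DataFrame(columns=["gene", "mask", "p", "p_corrected",
                                     "n_carriers", "n_het_carriers"])
    df = pd.DataFrame([{"gene": r.gene, "mask": r.mask, "p": r.p,
                        "p_corrected": r.p_corrected, "n_carriers": r.n_carriers,
                        "n_het_carriers": r.n_het_carriers} for r in rows])
    return (df.sort_values(["gene", "p_corrected"])
              .groupby("gene", as_index=False).first())


def results_table(results) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene": r.gene, "mask": r.mask, "n_carriers": r.n_carriers,
        "n_het_carriers": r.n_het_carriers, "n_variants": r.n_variants,
        "beta": r.beta, "se": r.se, "p": r.p, "p_corrected": r.p_corrected,
        "hit": r.hit, "filter_reasons": ";".join(r.filter_reasons),
    } for r in results])
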