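"""Novelty post-processing of association results.

A score locus is *known* when it colocalizes (shared-causal-variant posterior
PP4 above threshold) with any score-component biomarker that itself reaches
genome-wide significance inside the locus; otherwise it is *novel*.  Novel
loci are mapped to candidate causal genes via an externally supplied
per-gene causal-probability table; burden hits are novel when absent from
every component biomarker's own hit list.

Colocalization uses the standard single-causal-variant enumeration over
approximate Bayes factors (Wakefield's asymptotic ABF per variant), with the
five hypotheses: H0 no association, H1/H2 one trait only, H3 two distinct
causal variants, H4 one shared causal variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .gwas import GENOME_WIDE_SIG, Locus

#: default priors: per-variant probability of association with trait 1, with
#: trait 2, and with both; W is the prior effect variance of a quantitative
#: trait on the standardized scale
DEFAULT_PRIORS = {"p1": 1e-4, "p2": 1e-4, "p12": 1e-5}
DEFAULT_W = 0.15 ** 2


@dataclass
class ColocPosterior:
    """Posterior over the five colocalization hypotheses for one locus."""

    pp: np.ndarray  # PP0..PP4
    n_variants: int
    priors: dict
    w: float
    locus_id: str = ""
    trait_pair: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        if abs(float(self.pp.sum()) - 1.0) > 1e-9:
            raise ValueError("colocalization posteriors must sum to 1")

    @property
    def pp4(self) -> float:
        return float(self.pp[4])


def harmonize(stats1: pd.DataFrame, stats2: pd.DataFrame) -> pd.DataFrame:
    """Inner-join two summary-statistic slices on (CHR, POS), matching
    alleles either directly or flipped; a flipped match reverses the sign of
    the second trait's effect (Z² is what the ABF uses, but signs matter for
    any directional diagnostics)."""
    m = stats1.merge(stats2, on=["CHR", "POS"], suffixes=("_1", "_2"))
    direct = (m["EA_1"] == m["EA_2"]) & (m["OA_1"] == m["OA_2"])
    flipped = (m["EA_1"] == m["OA_2"]) & (m["OA_1"] == m["EA_2"])
    m = m.loc[direct | flipped].copy()
    flip = flipped.loc[m.index]
    m.loc[flip, "BETA_2"] = -m.loc[flip, "BETA_2"]
    m.loc[flip, "Z_2"] = -m.loc[flip, "Z_2"]
    return m


def _labf(beta: np.ndarray, se: np.ndarray, w: float) -> np.ndarray:
    """Wakefield log approximate Bayes factor per variant."""
    v = se ** 2
    z2 = (beta / se) ** 2
    r = w / (v + w)
    return 0.5 * (np.log1p(-r) + z2 * r)


def coloc_abf(
    stats1: pd.DataFrame,
    stats2: pd.DataFrame,
    priors: dict | None = None,
    w: float = DEFAULT_W,
    locus_id: str = "",
    trait_pair: tuple[str, str] = ("", ""),
) -> ColocPosterior:
    """Single-causal-variant colocalization of two traits over one region.

    Per-variant log ABFs are combined into the five hypothesis sums (log
    scale throughout, normalized by log-sum-exp):

    * H1 ∝ p1 · Σᵥ ABF1ᵥ, H2 ∝ p2 · Σᵥ ABF2ᵥ
    * H3 ∝ p1·p2 · (Σᵥ ABF1ᵥ · Σᵤ ABF2ᵤ − Σᵥ ABF1ᵥ·ABF2ᵥ)
    * H4 ∝ p12 · Σᵥ ABF1ᵥ·ABF2ᵥ, H0 ∝ 1.
    """
    pri = dict(DEFAULT_PRIORS, **(priors or {}))
    m = harmonize(stats1, stats2)
    m = m.loc[(m["SE_1"] > 0) & (m["SE_2"] > 0)]
    if m.empty:
        raise ValueError("no shared variants between the two traits")
    l1 = _labf(m["BETA_1"].to_numpy(float), m["SE_1"].to_numpy(float), w)
    l2 = _labf(m["BETA_2"].to_numpy(float), m["SE_2"].to_numpy(float), w)
    s1, s2, s12 = logsumexp(l1), logsumexp(l2), logsumexp(l1 + l2)
    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = np.log(pri["p1"]) + s1
    lh[2] = np.log(pri["p2"]) + s2
    # all ordered distinct pairs: full cross product minus the shared diagonal
    with np.errstate(divide="ignore"):
        gap = s12 - (s1 + s2)
        cross = s1 + s2 + (np.log1p(-np.exp(gap)) if gap < 0 else -np.inf)
    lh[3] = np.log(pri["p1"]) + np.log(pri["p2"]) + cross
    lh[4] = np.log(pri["p12"]) + s12
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    return ColocPosterior(pp=pp, n_variants=len(m), priors=pri, w=w,
                          locus_id=locus_id, trait_pair=trait_pair)


@dataclass
class NoveltyPartition:
    """Known/novel partition of score loci with a per-component decision trace."""

    novel: list[Locus]
    known: list[Locus]
    trace: pd.DataFrame  # locus_id, component, pp4, decision


def novelty_filter_snp(
    loci,
    score_stats: pd.DataFrame,
    component_stats: dict[str, pd.DataFrame],
    h4_threshold: float = 0.5,
    sig_threshold: float = GENOME_WIDE_SIG,
    priors: dict | None = None,
    w: float = DEFAULT_W,
) -> NoveltyPartition:
    """Label each score locus known or novel via component colocalization.

    Colocalization runs only against components with at least one genome-wide
    significant variant inside the locus; a locus is known iff any such run
    gives PP4 strictly above ``h4_threshold``.  A locus with no significant
    component is novel by vacuity; a failed colocalization is recorded and
    treated as non-colocalizing (novel), with a warning decision in the trace.
    """
    novel, known, rows = [], [], []
    for locus in loci:
        in_locus = ((score_stats["CHR"].astype(str) == locus.chrom)
                    & score_stats["POS"].between(locus.start, locus.end))
        s_slice = score_stats.loc[in_locus]
        is_known = False
        for name, comp in component_stats.items():
            c_in = ((comp["CHR"].astype(str) == locus.chrom)
                    & comp["POS"].between(locus.start, locus.end))
            c_slice = comp.loc[c_in]
            if c_slice.empty or float(c_slice["P"].min()) >= sig_threshold:
                continue
            try:
                post = coloc_abf(s_slice, c_slice, priors=priors, w=w,
                                 locus_id=locus.locus_id, trait_pair=("score", name))
            except ValueError:
                rows.append({"locus_id": locus.locus_id, "component": name,
                             "pp4": np.nan, "decision": "coloc_failed"})
                continue
            colocalized = post.pp4 > h4_threshold
            rows.append({"locus_id": locus.locus_id, "component": name,
                         "pp4": post.pp4,
                         "decision": "known" if colocalized else "independent"})
            is_known = is_known or colocalized
        (known if is_known else novel).append(locus)
        if not any(r["locus_id"] == locus.locus_id for r in rows):
            rows.append({"locus_id": locus.locus_id, "component": "",
                         "pp4": np.nan, "decision": "no_significant_component"})
    trace = pd.DataFrame(rows, columns=["locus_id", "component", "pp4", "decision"])
    return NoveltyPartition(novel=novel, known=known, trace=trace)


@dataclass
class GenePriority:
    """Causal-gene assignment for one locus."""

    locus_id: str
    candidates: dict[str, float]
    mapped_gene: str | None
    mapped: bool
    note: str = ""


def prioritize_genes(loci, gene_probabilities: pd.DataFrame,
                     threshold: float = 0.5) -> list[GenePriority]:
    """Per locus, map the unique maximum-probability gene when its causal
    probability is strictly above ``threshold``; ties at the maximum are
    ambiguous (not mapped); loci with no qualifying gene stay unmapped."""
    probs = gene_probabilities
    if ((probs["probability"] < 0) | (probs["probability"] > 1)).any():
        raise ValueError("gene probabilities must lie in [0, 1]")
    out = []
    for locus in loci:
        block = probs.loc[probs["locus_id"] == locus.locus_id]
        if block["gene"].duplicated().any():
            raise ValueError(f"duplicate gene entries for locus {locus.locus_id}")
        cand = dict(zip(block["gene"], block["probability"].astype(float)))
        if not cand:
            out.append(GenePriority(locus.locus_id, cand, None, False, "no_candidates"))
            continue
        top = max(cand.values())
        best = [g for g, p in cand.items() if p == top]
        if top <= threshold:
            out.append(GenePriority(locus.locus_id, cand, None, False, "below_threshold"))
        elif len(best) > 1:
            out.append(GenePriority(locus.locus_id, cand, None, False, "ambiguous_tie"))
        else:
            out.append(GenePriority(locus.locus_id, cand, best[0], True))
    return out


def novelty_filter_burden(
    score_hits, component_hits: dict[str, set]
) -> tuple[list[str], dict[str, list[str]]]:
    """Retain score burden hits absent from every component's hit set.

    Returns the sorted novel gene list and, for each discarded gene, the
    components whose hit lists contained it.
    """
    discarded: dict[str, list[str]] = {}
    novel = []
    for gene in sorted(set(score_hits)):
        matches = sorted(name for name, genes in component_hits.items() if gene in genes)
        if matches:
            discarded[gene] = matches
        else:
            novel.append(gene)
    return novel, discarded


def priorities_table(priorities) -> pd.DataFrame:
    return pd.DataFrame([{
        "locus_id": p.locus_id, "mapped_gene": p.mapped_gene or "",
        "probability": p.candidates.get(p.mapped_gene, np.nan) if p.mapped else np.nan,
        "mapped": p.mapped, "note": p.note,
    } for p in priorities])
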