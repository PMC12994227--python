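"""Per-variant association of the transferred score and summary-statistic
post-processing: locus definition by significance chaining, tail-quantile
genomic-inflation estimation, Z-score deflation, and locus redefinition on
the adjusted p-values.

Summary statistics live in a plain DataFrame with the GWAS-SSF-like columns
``CHR, POS, ID, EA, OA, EAF, BETA, SE, Z, P, N`` (plus ``FLAG`` marking
monomorphic/failed variants, which never enter the inflation estimate).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

SUMSTATS_COLUMNS = ["CHR", "POS", "ID", "EA", "OA", "EAF", "BETA", "SE", "Z", "P", "N", "FLAG"]

#: conventional genome-wide significance threshold for a single variant
GENOME_WIDE_SIG = 5e-8


def _residualize(v: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residual of v on [1, covariates] via least squares."""
    n = v.shape[0]
    x = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    coef, *_ = np.linalg.lstsq(x, v, rcond=None)
    return v - x @ coef


def run_variant_association(scores, genotypes, covariates=None) -> pd.DataFrame:
    """Ordinary least squares of the score on each variant's allele count,
    adjusted for ``covariates`` (vectorized across variants).

    A desk-scale single-variant scan: genotype and phenotype are residualized
    on the covariates, then each variant is a simple regression on the
    residuals, with the residual degrees of freedom accounting for the
    covariates.  Monomorphic variants are emitted with p = 1 and a flag.
    """
    y = np.asarray(scores, dtype=float)
    g = genotypes.matrix.astype(float)
    n = len(y)
    if g.shape[0] != n:
        raise ValueError("scores and genotypes have mismatched subject counts")
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    n_cov = 1 + (0 if cov is None else cov.shape[1])

    yr = _residualize(y, cov)
    gr = g - g.mean(axis=0)
    if cov is not None:
        x = np.column_stack([np.ones(n), cov])
        coef, *_ = np.linalg.lstsq(x, g, rcond=None)
        gr = g - x @ coef

    sxx = (gr ** 2).sum(axis=0)
    sxy = gr.T @ yr
    mono = sxx <= 1e-12
    sxx_safe = np.where(mono, 1.0, sxx)
    beta = sxy / sxx_safe
    df = n - n_cov - 1
    rss = (yr ** 2).sum() - beta ** 2 * sxx
    se = np.sqrt(np.maximum(rss, 0.0) / max(df, 1) / sxx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    beta[mono], se[mono], z[mono], p[mono] = 0.0, np.nan, 0.0, 1.0
    return pd.DataFrame({
        "CHR": genotypes.chrom, "POS": genotypes.pos, "ID": genotypes.variant_ids,
        "EA": genotypes.ea, "OA": genotypes.oa, "EAF": g.mean(axis=0) / 2.0,
        "BETA": beta, "SE": se, "Z": z, "P": np.clip(p, 1e-320, 1.0), "N": n,
        "FLAG": np.where(mono, "monomorphic", ""),
    })


@dataclass
class Locus:
    """Contiguous genomic interval of chained significant variants plus
    flanks; 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    lead_id: str
    lead_p: float
    members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError("invalid locus interval")

    @property
    def n_sig(self) -> int:
        return len(self.members)

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def contains(self, chrom, pos) -> bool:
        return str(chrom) == self.chrom and self.start <= pos <= self.end


def _chrom_sort_key(c: str):
    return (0, int(c)) if re.fullmatch(r"\d+", c) else (1, c)


def define_loci(
    sumstats: pd.DataFrame,
    sig_threshold: float = GENOME_WIDE_SIG,
    flank_bp: int = 100_000,
    chain_gap_bp: int = 100_000,
) -> list[Locus]:
    """Chain genome-wide-significant variants into loci.

    Per chromosome, consecutive significant positions at most ``chain_gap_bp``
    apart belong to one locus; each locus is extended by ``flank_bp`` on both
    sides (clipped at position 1).  Flanked loci that overlap are merged so
    loci on a chromosome are pairwise disjoint and every significant variant
    lies in exactly one locus.  The lead variant is the minimum-p member.
    """
    sig = sumstats.loc[(sumstats["P"] < sig_threshold) & (sumstats["FLAG"] == "")]
    loci: list[Locus] = []
    for chrom in sorted(sig["CHR"].astype(str).unique(), key=_chrom_sort_key):
        block = sig.loc[sig["CHR"].astype(str) == chrom].sort_values("POS")
        pos = block["POS"].to_numpy(np.int64)
        breaks = np.flatnonzero(np.diff(pos) > chain_gap_bp) + 1
        for chunk in np.split(np.arange(len(pos)), breaks):
            sub = block.iloc[chunk]
            start = max(1, int(sub["POS"].iloc[0]) - flank_bp)
            end = int(sub["POS"].iloc[-1]) + flank_bp
            lead = sub.loc[sub["P"].idxmin()]
            locus = Locus(chrom=chrom, start=start, end=end,
                          lead_id=str(lead["ID"]), lead_p=float(lead["P"]),
                          members=sub["ID"].astype(str).tolist())
            if loci and loci[-1].chrom == chrom and locus.start <= loci[-1].end:
                prev = loci[-1]  # flanks overlap: merge into one disjoint locus
                prev.end = max(prev.end, locus.end)
                prev.members += locus.members
                if locus.lead_p < prev.lead_p:
                    prev.lead_id, prev.lead_p = locus.lead_id, locus.lead_p
            else:
                loci.append(locus)
    return loci


def loci_table(loci) -> pd.DataFrame:
    return pd.DataFrame(
        [{"CHR": l.chrom, "START": l.start, "END": l.end, "LEAD_ID": l.lead_id,
          "LEAD_P": l.lead_p, "N_SIG": l.n_sig} for l in loci],
        columns=["CHR", "START", "END", "LEAD_ID", "LEAD_P", "N_SIG"],
    )


def _outside_locus_mask(sumstats: pd.DataFrame, loci) -> np.ndarray:
    inside = np.zeros(len(sumstats), dtype=bool)
    chroms = sumstats["CHR"].astype(str).to_numpy()
    pos = sumstats["POS"].to_numpy(np.int64)
    for locus in loci:
        inside |= (chroms == locus.chrom) & (pos >= locus.start) & (pos <= locus.end)
    return ~inside


@dataclass
class InflationAdjustment:
    """Tail-quantile genomic-inflation estimate computed outside significant
    loci: λ = empirical χ² quantile / theoretical χ²₁ quantile."""

    lambda_: float
    quantile: float
    n_variants: int

    @property
    def applied(self) -> bool:
        return self.lambda_ > 1.0


def inflation_factor(
    sumstats: pd.DataFrame, loci, quantile: float = 0.99, min_variants: int = 100
) -> InflationAdjustment:
    """λ from variants outside significant loci.

    The upper ``quantile`` of the observed χ² = Z² distribution (default 0.99,
    i.e. the 1st percentile of p-values) is divided by the matching
    theoretical χ²₁ quantile (6.6349 at 0.99).  Flagged variants are excluded.
    """
    ok = (sumstats["FLAG"] == "") & _outside_locus_mask(sumstats, loci)
    chi2 = sumstats.loc[ok, "Z"].to_numpy(float) ** 2
    if len(chi2) < min_variants:
        raise ValueError(f"only {len(chi2)} variants outside loci; need >= {min_variants}")
    lam = float(np.quantile(chi2, quantile) / stats.chi2.ppf(quantile, df=1))
    return InflationAdjustment(lambda_=lam, quantile=quantile, n_variants=len(chi2))


def adjust_zscores(
    sumstats: pd.DataFrame, adj: InflationAdjustment, gc_mode: str = "z_over_lambda"
) -> pd.DataFrame:
    """Deflate Z and recompute p for *all* variants when λ > 1; identity
    otherwise.

    ``gc_mode="z_over_lambda"`` divides Z by λ; ``"z_over_sqrt_lambda"`` is
    the classic genomic-control convention dividing by √λ.
    """
    if gc_mode not in ("z_over_lambda", "z_over_sqrt_lambda"):
        raise ValueError(f"unknown gc_mode {gc_mode!r}")
    out = sumstats.copy()
    if not adj.applied:
        return out
    denom = adj.lambda_ if gc_mode == "z_over_lambda" else np.sqrt(adj.lambda_)
    z = out["Z"].to_numpy(float) / denom
    p = 2.0 * stats.norm.sf(np.abs(z))
    flagged = out["FLAG"].to_numpy() != ""
    out["Z"] = np.where(flagged, out["Z"], z)
    out["P"] = np.where(flagged, out["P"], np.clip(p, 1e-320, 1.0))
    return out


def redefine_loci_after_adjustment(sumstats_adjusted: pd.DataFrame, **kwargs) -> list[Locus]:
    """Locus definition re-run on inflation-adjusted p-values (same contract
    as :func:`define_loci`)."""
    return define_loci(sumstats_adjusted, **kwargs)


def write_sumstats(sumstats: pd.DataFrame, path) -> None:
    sumstats.to_csv(path, sep="\t", index=False)


def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    df["FLAG"] = df.get("FLAG", pd.Series([""] * len(df))).fillna("")
    if "Z" not in df.columns:
        df["Z"] = df["BETA"] / df["SE"]
    return df
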