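"""Independent oracles used by the test suite.

Each oracle is a deliberately naive re-derivation of a quantity the package
computes by other means: a Newton solver on the Cox partial likelihood, an
exhaustive pair enumeration for the concordance index, and an interval-merge
reconstruction of locus definition.  They share no code with the package
internals they check.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def cox_newton(x: np.ndarray, time: np.ndarray, event: np.ndarray,
               tol: float = 1e-12, max_iter: int = 200):
    """Newton–Raphson maximum of the Cox partial likelihood (Breslow form;
    fixtures must have no tied event times, where Breslow = Efron = exact).

    Returns (beta, se) with se from the inverse observed information.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    order = np.argsort(time, kind="stable")
    x, t, e = x[order], np.asarray(time, float)[order], np.asarray(event, int)[order]
    n, p = x.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = x @ beta
        w = np.exp(eta - eta.max())
        score = np.zeros(p)
        info = np.zeros((p, p))
        for i in np.flatnonzero(e == 1):
            risk = slice(i, n)  # t sorted ascending: risk set = later-or-equal
            wr = w[risk]
            s0 = wr.sum()
            s1 = wr @ x[risk]
            s2 = (wr[:, None] * x[risk]).T @ x[risk]
            xbar = s1 / s0
            score += x[i] - xbar
            info += s2 / s0 - np.outer(xbar, xbar)
        step = np.linalg.solve(info, score)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se


def cox_wald_p(beta: float, se: float) -> float:
    return 2.0 * stats.norm.sf(abs(beta / se))


def concordance_enumeration(scores, time, event):
    """O(n²) pair-by-pair Harrell's C.

    A pair is comparable when the earlier observed time carries an event
    (ties: event-vs-censored at the same time is comparable with the event
    first; event-vs-event at the same time is not).  Concordant = higher
    score on the earlier event; score ties count 1/2.
    """
    s = np.asarray(scores, float)
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    num = comp = 0.0
    n = len(s)
    for i in range(n):
        for j in range(i + 1, n):
            if t[i] == t[j]:
                if e[i] == e[j]:
                    continue
                first, second = (i, j) if e[i] == 1 else (j, i)
            elif t[i] < t[j]:
                if e[i] == 0:
                    continue
                first, second = i, j
            else:
                if e[j] == 0:
                    continue
                first, second = j, i
            comp += 1
            if s[first] > s[second]:
                num += 1.0
            elif s[first] == s[second]:
                num += 0.5
    if comp == 0:
        raise ValueError("no comparable pairs")
    return num / comp, int(comp)


def loci_interval_merge(sumstats, sig_threshold=5e-8, flank_bp=100_000,
                        chain_gap_bp=100_000):
    """Reconstruct loci as (chrom, start, end, members, lead) tuples.

    Consecutive significant positions merge when their gap is at most
    max(chain_gap_bp, 2*flank_bp): the chaining rule joins gaps up to the
    chain gap, and flank overlap joins anything closer than two flanks.
    """
    out = []
    sig = sumstats[(sumstats["P"] < sig_threshold) & (sumstats["FLAG"] == "")]
    join = max(chain_gap_bp, 2 * flank_bp)
    for chrom in sig["CHR"].astype(str).unique():
        block = sig[sig["CHR"].astype(str) == chrom].sort_values("POS")
        group = []
        prev = None
        for _, row in block.iterrows():
            if prev is not None and row["POS"] - prev > join:
                out.append(_finish(chrom, group, flank_bp))
                group = []
            group.append(row)
            prev = row["POS"]
        if group:
            out.append(_finish(chrom, group, flank_bp))
    return out


def _finish(chrom, group, flank_bp):
    poss = [int(r["POS"]) for r in group]
    ps = [float(r["P"]) for r in group]
    lead = group[int(np.argmin(ps))]
    return {
        "chrom": chrom,
        "start": max(1, poss[0] - flank_bp),
        "end": poss[-1] + flank_bp,
        "members": [str(r["ID"]) for r in group],
        "lead_id": str(lead["ID"]),
        "lead_p": float(lead["P"]),
    }


def ols_closed_form(y, g, with_intercept=True):
    """Simple-regression slope and its standard error, textbook formulas."""
    y = np.asarray(y, float)
    g = np.asarray(g, float)
    n = len(y)
    gx = g - g.mean() if with_intercept else g
    yx = y - y.mean() if with_intercept else y
    sxx = (gx ** 2).sum()
    beta = (gx * yx).sum() / sxx
    resid = yx - beta * gx
    df = n - (2 if with_intercept else 1)
    se = np.sqrt((resid ** 2).sum() / df / sxx)
    return beta, se
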