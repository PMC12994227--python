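"""Discrimination assessment of a transferred risk score: Harrell's
concordance index under right censoring, plus the external-cohort subset
rules (eGFR floor, diabetes-only) applied before scoring.

Pair convention (standard Harrell):

* a pair is comparable when the earlier observed time belongs to a subject
  with an event (the ordering of the two outcomes is then known);
* two events at exactly the same time are non-comparable;
* an event tied in time with a censored subject is comparable — the censored
  subject is known to have survived at least as long;
* within a comparable pair, the higher score on the earlier event is
  concordant; tied scores count 1/2.

The index is computed by exact pair enumeration, vectorized in row chunks so
cohorts of tens of thousands of subjects stay within memory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable, apply_subset


@dataclass
class ValidationReport:
    """Concordance of a score in one cohort/subset."""

    cohort_label: str
    subset_rule: str
    n: int
    n_events: int
    c_index: float
    n_comparable: int

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort_label, "subset": self.subset_rule,
            "n": self.n, "n_events": self.n_events,
            "c_index": self.c_index, "n_comparable": self.n_comparable,
        }


def concordance_index(scores, time, event, _chunk: int = 512) -> tuple[float, int]:
    """Harrell's C: (concordant + tied/2) / comparable over all subject pairs.

    Returns ``(c, n_comparable)``; raises ``ValueError`` when no pair is
    comparable (e.g. fewer than two subjects or no events).
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if not (len(s) == len(t) == len(e)):
        raise ValueError("scores, time and event must have equal length")
    n = len(s)
    num = 0.0
    n_comp = 0
    for lo in range(0, n, _chunk):
        hi = min(lo + _chunk, n)
        ti, ei, si = t[lo:hi, None], e[lo:hi, None], s[lo:hi, None]
        # pair (i, j): i indexes the chunk rows, j all subjects
        earlier_i = (ti < t[None, :]) | ((ti == t[None, :]) & (e[None, :] == 0))
        comp_i = (ei == 1) & earlier_i          # i had the event first
        comp_i &= ~((ti == t[None, :]) & (ei == 1) & (e[None, :] == 1))
        # count each unordered pair once: restrict to j > global row index
        cols = np.arange(n)[None, :]
        rows = np.arange(lo, hi)[:, None]
        comp_j_first = (e[None, :] == 1) & (
            (t[None, :] < ti) | ((t[None, :] == ti) & (ei == 0)))
        upper = cols > rows
        comp_i &= upper
        comp_j_first &= upper
        n_comp += int(comp_i.sum() + comp_j_first.sum())
        num += np.where(si > s[None, :], 1.0, np.where(si == s[None, :], 0.5, 0.0))[comp_i].sum()
        num += np.where(s[None, :] > si, 1.0, np.where(si == s[None, :], 0.5, 0.0))[comp_j_first].sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs: concordance undefined")
    return float(num / n_comp), n_comp


def validate_score(
    results,
    cohort: CohortTable,
    egfr_min: float | None = None,
    require_diabetes: bool = False,
    label: str | None = None,
) -> ValidationReport:
    """Apply subset rules, score the remaining subjects with the *training*
    standardization frozen in ``results``, and report Harrell's C."""
    sub = apply_subset(cohort, egfr_min=egfr_min, require_diabetes=require_diabetes)
    scores = results.predict(sub)
    idx = scores.index
    c, n_comp = concordance_index(
        scores.to_numpy(),
        sub.data.loc[idx, "time"].to_numpy(float),
        sub.data.loc[idx, "event"].to_numpy(int),
    )
    parts = []
    if egfr_min is not None:
        parts.append(f"eGFR>{egfr_min:g}")
    if require_diabetes:
        parts.append("diabetes")
    return ValidationReport(
        cohort_label=label if label is not None else cohort.label,
        subset_rule="+".join(parts) or "all",
        n=len(idx),
        n_events=int(sub.data.loc[idx, "event"].sum()),
        c_index=c,
        n_comparable=n_comp,
    )


def report_table(reports) -> pd.DataFrame:
    """Stack validation reports into a tidy table (rows: cohort/subset)."""
    return pd.DataFrame([r.to_dict() for r in reports])
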