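"""Subject-level cohort container and table-level operations.

A :class:`CohortTable` wraps a pandas DataFrame holding one row per subject:
an identifier, demographics (age in years, sex as a 0/1 indicator), a study
label, the survival outcome (follow-up time > 0 and an event indicator), and
one column per baseline biomarker.  Every biomarker column carries a declared
unit tag so that measurements can be aligned across cohorts before a model is
transferred between them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: required non-biomarker columns
CORE_COLUMNS = ("id", "age", "sex", "study", "time", "event")


@dataclass
class AffineConversion:
    """Unit conversion ``new = scale * old + offset`` with a target unit tag."""

    scale: float
    offset: float = 0.0
    unit: str = ""

    def __post_init__(self) -> None:
        if self.scale == 0:
            raise ValueError("affine conversion requires a nonzero scale")


@dataclass
class CohortTable:
    """Subject-level cohort: outcome, demographics and baseline biomarkers.

    Parameters
    ----------
    data:
        DataFrame with the columns in :data:`CORE_COLUMNS` plus one column per
        biomarker (and optionally extra columns such as an eGFR measurement or
        a diabetes flag used for subsetting).
    biomarkers:
        Names of the biomarker columns, in no particular order.
    units:
        Unit tag per biomarker.  Biomarkers without an entry default to
        ``"standardized"``.
    urine:
        Flags marking urine-derived biomarkers; used to restrict the candidate
        set when building a blood-only ("non-urine") score.
    label:
        Free-form cohort label (e.g. ``"trial"``, ``"external"``).
    """

    data: pd.DataFrame
    biomarkers: list[str]
    units: dict[str, str] = field(default_factory=dict)
    urine: dict[str, bool] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in CORE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table missing required columns: {missing}")
        absent = [b for b in self.biomarkers if b not in self.data.columns]
        if absent:
            raise ValueError(f"declared biomarkers absent from table: {absent}")
        t = self.data["time"].to_numpy(float)
        if np.any(t[np.isfinite(t)] <= 0):
            raise ValueError("follow-up times must be strictly positive")
        ev = self.data["event"].dropna().unique()
        if not set(np.asarray(ev, dtype=float)) <= {0.0, 1.0}:
            raise ValueError("event indicator must be 0/1")
        for b in self.biomarkers:
            self.units.setdefault(b, "standardized")
            self.urine.setdefault(b, False)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())

    def subset(self, mask: np.ndarray | pd.Series) -> "CohortTable":
        return replace(self, data=self.data.loc[mask].reset_index(drop=True))

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path) -> None:
        """Write the table as TSV with unit/urine metadata in '#' header lines."""
        with open(path, "w") as fh:
            fh.write(f"#label\t{self.label}\n")
            fh.write("#biomarkers\t" + ",".join(self.biomarkers) + "\n")
            units = ",".join(f"{b}={self.units[b]}" for b in self.biomarkers)
            fh.write(f"#units\t{units}\n")
            urine = ",".join(b for b in self.biomarkers if self.urine[b])
            fh.write(f"#urine\t{urine}\n")
            self.data.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CohortTable":
        meta: dict[str, str] = {}
        skip = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, value = line[1:].rstrip("\n").partition("\t")
                meta[key] = value
                skip += 1
        data = pd.read_csv(path, sep="\t", skiprows=skip,
                           dtype={"id": str, "study": str})
        biomarkers = [b for b in meta.get("biomarkers", "").split(",") if b]
        units = dict(kv.split("=", 1) for kv in meta.get("units", "").split(",") if "=" in kv)
        urine_set = {b for b in meta.get("urine", "").split(",") if b}
        return cls(
            data=data,
            biomarkers=biomarkers,
            units=units,
            urine={b: b in urine_set for b in biomarkers},
            label=meta.get("label", ""),
        )


def align_units(table: CohortTable, conversions: dict[str, AffineConversion]) -> CohortTable:
    """Apply per-variable affine unit conversions; untouched variables pass through.

    Raises ``KeyError`` for a conversion naming an absent column and
    ``ValueError`` for a zero scale (enforced by :class:`AffineConversion`).
    """
    unknown = [v for v in conversions if v not in table.data.columns]
    if unknown:
        raise KeyError(f"conversion names absent columns: {unknown}")
    data = table.data.copy()
    units = dict(table.units)
    for var, conv in conversions.items():
        data[var] = conv.scale * data[var] + conv.offset
        if var in units:
            units[var] = conv.unit or units[var]
    return replace(table, data=data, units=units)


def split_train_test(table: CohortTable, fraction: float, seed: int) -> tuple[CohortTable, CohortTable]:
    """Random disjoint, exhaustive split; training size is ``ceil(fraction * N)``."""
    if not 0 < fraction < 1:
        raise ValueError("split fraction must lie strictly between 0 and 1")
    n = len(table)
    n_train = math.ceil(fraction * n)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = table.data.iloc[np.sort(perm[:n_train])].reset_index(drop=True)
    test = table.data.iloc[np.sort(perm[n_train:])].reset_index(drop=True)
    return replace(table, data=train), replace(table, data=test)


def apply_subset(
    table: CohortTable,
    egfr_min: float | None = None,
    require_diabetes: bool = False,
    egfr_col: str = "egfr",
    diabetes_col: str = "diabetes",
) -> CohortTable:
    """Filter subjects for external validation.

    ``egfr_min`` keeps subjects with a baseline eGFR strictly greater than the
    cutoff (late-stage disease excluded so progression remains observable);
    ``require_diabetes`` keeps subjects flagged diabetic at baseline.  Subjects
    with a missing value in a filter column are excluded, with a logged count.
    """
    mask = pd.Series(True, index=table.data.index)
    n_missing = 0
    if egfr_min is not None:
        if egfr_col not in table.data.columns:
            raise KeyError(f"eGFR filter requested but column {egfr_col!r} absent")
        egfr = table.data[egfr_col]
        n_missing += int((egfr.isna() & mask).sum())
        mask &= egfr.notna() & (egfr > egfr_min)
    if require_diabetes:
        if diabetes_col not in table.data.columns:
            raise KeyError(f"diabetes filter requested but column {diabetes_col!r} absent")
        dm = table.data[diabetes_col]
        n_missing += int((dm.isna() & mask).sum())
        mask &= dm.notna() & (dm.astype(float) > 0)
    if n_missing:
        logger.info("apply_subset: dropped %d subjects with missing filter values", n_missing)
    return table.subset(mask)
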