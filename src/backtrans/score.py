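"""Clinical risk-score construction: standardization, univariate Cox screen,
BIC forward selection, and the final transferable linear score.

The model follows the classic two-stage recipe for building a parsimonious
Cox score from a trial cohort:

1. every candidate biomarker is screened in a univariate Cox model adjusted
   for age, sex and study (Wald p of the biomarker coefficient < 0.1 keeps
   the candidate);
2. greedy forward selection over the screened set minimizes the Bayesian
   Information Criterion of the multivariate Cox fit, stopping when no
   addition improves it;
3. the final score is the coefficient-weighted sum of the selected,
   z-standardized variables — no baseline-hazard term, so it transfers to
   any cohort carrying the same measurements.

Training centers and scales are serialized with the coefficients and are
reused verbatim on every downstream cohort: the score is a frozen linear
functional of the raw measurements.

Partial-likelihood fitting is delegated to lifelines (Efron ties); the
screen, selection and scoring logic live here.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .cohort import CohortTable

logger = logging.getLogger(__name__)

ADJUSTMENT_VARS = ("age", "sex")  # study enters separately, dummy-coded


def standardization_params(cohort: CohortTable, variables) -> dict[str, tuple[float, float]]:
    """Training-data z-score parameters: (mean, SD) per continuous variable;
    the binary sex indicator passes through with (0, 1)."""
    params: dict[str, tuple[float, float]] = {}
    for v in variables:
        if v == "sex":
            params[v] = (0.0, 1.0)
            continue
        col = cohort.data[v].astype(float)
        sd = float(col.std(ddof=0))
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"variable {v!r} is constant; cannot standardize")
        params[v] = (float(col.mean()), sd)
    return params


def _standardized_columns(cohort: CohortTable, variables, params) -> pd.DataFrame:
    out = {}
    for v in variables:
        center, scale = params[v]
        out[v] = (cohort.data[v].astype(float) - center) / scale
    return pd.DataFrame(out, index=cohort.data.index)


def _study_dummies(cohort: CohortTable) -> pd.DataFrame:
    dummies = pd.get_dummies(cohort.data["study"].astype(str), prefix="study",
                             drop_first=True, dtype=float)
    return dummies


def _fit_cox(design: pd.DataFrame, polish: bool = False) -> CoxPHFitter:
    cph = CoxPHFitter()
    cph.fit(design, duration_col="time", event_col="event")
    if polish:
        # warm-restart Newton polish: the solver's relative log-likelihood
        # stopping rule leaves ~1e-7 residual error in the coefficients;
        # one restart from the optimum squares it away.  Used where the
        # numbers are reported or serialized, not inside selection loops.
        start = cph.params_.to_numpy()
        cph = CoxPHFitter()
        cph.fit(design, duration_col="time", event_col="event",
                initial_point=start, fit_options={"precision": 1e-11})
    return cph


@dataclass
class ScreenResult:
    """Univariate screen outcome: per-candidate coefficient (per standardized
    unit), Wald p-value and the selected flag (p < threshold)."""

    table: pd.DataFrame  # columns: variable, coef, se, p, selected
    threshold: float

    @property
    def selected(self) -> list[str]:
        return self.table.loc[self.table["selected"], "variable"].tolist()


def univariate_screen(
    cohort: CohortTable,
    candidates,
    threshold: float = 0.1,
    params: dict | None = None,
) -> ScreenResult:
    """Screen each candidate in a Cox model adjusted for age, sex and study.

    Non-converging or constant candidates are excluded with a warning and a
    NaN row (never silently dropped).
    """
    candidates = list(candidates)
    missing = [c for c in candidates if c not in cohort.data.columns]
    if missing:
        raise KeyError(f"screen candidates absent from cohort: {missing}")
    params = dict(params) if params else {}
    for a in ADJUSTMENT_VARS:
        if a not in params:
            params.update(standardization_params(cohort, [a]))
    dummies = _study_dummies(cohort)

    rows = []
    for cand in candidates:
        covs = [cand] + [a for a in ADJUSTMENT_VARS if a != cand]
        try:
            if cand not in params:
                params.update(standardization_params(cohort, [cand]))
            std = _standardized_columns(cohort, covs, params)
        except ValueError as err:
            logger.warning("screen: excluding %r (%s)", cand, err)
            rows.append({"variable": cand, "coef": np.nan, "se": np.nan,
                         "p": np.nan, "selected": False})
            continue
        design = pd.concat([std, dummies, cohort.data[["time", "event"]]], axis=1)
        try:
            cph = _fit_cox(design, polish=True)
        except ConvergenceError as err:
            logger.warning("screen: %r did not converge (%s)", cand, err)
            rows.append({"variable": cand, "coef": np.nan, "se": np.nan,
                         "p": np.nan, "selected": False})
            continue
        summ = cph.summary.loc[cand]
        p = float(summ["p"])
        rows.append({"variable": cand, "coef": float(summ["coef"]),
                     "se": float(summ["se(coef)"]), "p": p,
                     "selected": bool(p < threshold)})
    table = pd.DataFrame(rows, columns=["variable", "coef", "se", "p", "selected"])
    return ScreenResult(table=table, threshold=threshold)


def cox_bic(cohort: CohortTable, variables, params,
            polish: bool = False) -> tuple[float, CoxPHFitter | None]:
    """BIC of the multivariate Cox fit: −2·log partial likelihood + k·log(d),
    with d the number of events (the effective sample size in a Cox model)
    and k the number of fitted coefficients (study dummies included)."""
    dummies = _study_dummies(cohort)
    d = cohort.n_events
    if not variables and dummies.empty:
        raise ValueError("cox_bic requires at least one covariate; use _null_bic")
    std = _standardized_columns(cohort, variables, params)
    design = pd.concat([std, dummies, cohort.data[["time", "event"]]], axis=1)
    cph = _fit_cox(design, polish=polish)
    k = len(variables) + dummies.shape[1]
    return -2.0 * cph.log_likelihood_ + k * math.log(max(d, 1)), cph


def _null_bic(cohort: CohortTable, params) -> float:
    """BIC of the adjustment-only (study dummies, no score variable) model."""
    dummies = _study_dummies(cohort)
    d = cohort.n_events
    if dummies.empty:
        # no covariates at all: log partial likelihood of the empty model
        time = cohort.data["time"].to_numpy(float)
        event = cohort.data["event"].to_numpy(int)
        order = np.argsort(time)
        t, e = time[order], event[order]
        n = len(t)
        # Breslow null: ll = -sum over events of log(risk-set size); exact for
        # the covariate-free model (all relative hazards equal)
        risk = n - np.arange(n)
        ll = -float(np.sum(e * np.log(risk)))
        return -2.0 * ll
    design = pd.concat([dummies, cohort.data[["time", "event"]]], axis=1)
    cph = _fit_cox(design)
    return -2.0 * cph.log_likelihood_ + dummies.shape[1] * math.log(max(d, 1))


class RiskScoreModel:
    """Cox risk-score model over a training cohort.

    Parameters
    ----------
    cohort:
        Training :class:`~backtrans.cohort.CohortTable`.
    candidates:
        Candidate variables for the score.  Defaults to every biomarker of the
        cohort (restricted by ``variant``) plus age and sex, which are
        eligible — not forced — unless listed in ``force``.
    variant:
        ``"urine"`` keeps all biomarkers, ``"non-urine"`` drops urine-flagged
        ones (a blood-only score is easier to collect in practice).
    screen_threshold:
        Wald-p cutoff of the univariate screen (default 0.1).
    force:
        Variables included in the multivariate model from the first step.
    """

    def __init__(
        self,
        cohort: CohortTable,
        candidates=None,
        variant: str = "urine",
        screen_threshold: float = 0.1,
        include_age_sex: bool = True,
        force=(),
    ) -> None:
        if variant not in ("urine", "non-urine"):
            raise ValueError("variant must be 'urine' or 'non-urine'")
        self.cohort = cohort
        self.variant = variant
        self.screen_threshold = screen_threshold
        self.force = list(force)
        if candidates is None:
            candidates = [b for b in cohort.biomarkers
                          if variant == "urine" or not cohort.urine.get(b, False)]
            if include_age_sex:
                candidates += ["age", "sex"]
        self.candidates = list(candidates)
        if "study" in self.candidates:
            raise ValueError("study is an adjustment covariate, never a score candidate")

    def fit(self) -> "RiskScoreResults":
        params = standardization_params(self.cohort, ADJUSTMENT_VARS)
        for c in self.candidates:
            if c not in params:
                try:
                    params.update(standardization_params(self.cohort, [c]))
                except ValueError as err:
                    logger.warning("fit: excluding %r (%s)", c, err)
        screen = univariate_screen(self.cohort, self.candidates,
                                   self.screen_threshold, params=params)
        pool = [v for v in screen.selected if v not in self.force]
        selected, trace, status = self._forward_select(pool, params)
        order = self.force + selected
        if order:
            _, cph = cox_bic(self.cohort, order, params, polish=True)
            coefs = pd.Series({v: float(cph.params_[v]) for v in order})
        else:
            coefs = pd.Series(dtype=float)
            status = status or "empty-model"
        return RiskScoreResults(
            variant_tag=self.variant,
            selected=order,
            coefficients=coefs,
            standardization={v: params[v] for v in order},
            screen=screen,
            trace=trace,
            status=status or "ok",
            n=len(self.cohort),
            n_events=self.cohort.n_events,
        )

    def _forward_select(self, pool, params):
        """Greedy BIC forward selection; stops when no addition improves BIC."""
        current = list(self.force)
        if current:
            best_bic, _ = cox_bic(self.cohort, current, params)
        else:
            best_bic = _null_bic(self.cohort, params)
        remaining = list(pool)
        selected: list[str] = []
        trace = [{"step": 0, "added": None, "bic": best_bic}]
        while remaining:
            scores = []
            for v in remaining:
                try:
                    bic, _ = cox_bic(self.cohort, current + [v], params)
                except ConvergenceError:
                    logger.warning("forward selection: %r did not converge; skipped", v)
                    continue
                scores.append((bic, v))
            if not scores:
                break
            bic, best = min(scores, key=lambda t: (t[0], t[1]))
            if bic >= best_bic:
                break
            current.append(best)
            selected.append(best)
            remaining.remove(best)
            best_bic = bic
            trace.append({"step": len(trace), "added": best, "bic": bic})
        status = "" if (selected or self.force) else "no-variable-improves-null"
        return selected, trace, status


@dataclass
class RiskScoreResults:
    """Fitted, transferable risk score.

    ``coefficients`` are log hazard ratios per standardized unit of each
    selected variable; ``standardization`` holds the *training* (center,
    scale) pairs that must be reused verbatim on any cohort the score is
    transferred to.
    """

    variant_tag: str
    selected: list[str]
    coefficients: pd.Series
    standardization: dict[str, tuple[float, float]]
    screen: ScreenResult | None = None
    trace: list[dict] = field(default_factory=list)
    status: str = "ok"
    n: int = 0
    n_events: int = 0

    def __post_init__(self) -> None:
        missing = [v for v in self.coefficients.index if v not in self.standardization]
        if missing:
            raise ValueError(f"coefficients without standardization entries: {missing}")

    def predict(self, cohort: CohortTable) -> pd.Series:
        """Risk score R_i = Σ_j β̂_j · (y_ij − center_j)/scale_j.

        Subjects with a missing value in any selected variable are dropped
        from the returned Series, with a logged count (no imputation).
        """
        if not self.selected:
            return pd.Series(np.zeros(len(cohort)), index=cohort.data.index, name="score")
        missing_cols = [v for v in self.selected if v not in cohort.data.columns]
        if missing_cols:
            raise KeyError(f"cohort lacks score variables: {missing_cols}")
        block = cohort.data[self.selected].astype(float)
        complete = block.notna().all(axis=1)
        n_drop = int((~complete).sum())
        if n_drop:
            logger.info("predict: dropped %d subjects with missing score variables", n_drop)
        block = block.loc[complete]
        score = np.zeros(len(block))
        for v in self.selected:
            center, scale = self.standardization[v]
            score += self.coefficients[v] * (block[v].to_numpy() - center) / scale
        return pd.Series(score, index=block.index, name="score")

    def summary(self) -> str:
        lines = [
            f"Risk score ({self.variant_tag} variant)  "
            f"n={self.n}, events={self.n_events}, status={self.status}",
            f"{'variable':<16}{'coef':>10}{'center':>12}{'scale':>10}",
        ]
        for v in self.selected:
            c, s = self.standardization[v]
            lines.append(f"{v:<16}{self.coefficients[v]:>10.5f}{c:>12.4f}{s:>10.4f}")
        lines.append("selection trace (BIC): " +
                     " -> ".join(f"{t['added'] or 'null'}:{t['bic']:.2f}" for t in self.trace))
        return "\n".join(lines)

    # ------------------------------------------------------------ serialization
    def to_json(self, path) -> None:
        payload = {
            "variant_tag": self.variant_tag,
            "selected": self.selected,
            "coefficients": {v: float(self.coefficients[v]) for v in self.selected},
            "standardization": {v: list(map(float, self.standardization[v]))
                                for v in self.selected},
            "trace": self.trace,
            "status": self.status,
            "n": self.n,
            "n_events": self.n_events,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RiskScoreResults":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            variant_tag=payload["variant_tag"],
            selected=payload["selected"],
            coefficients=pd.Series(payload["coefficients"], dtype=float),
            standardization={v: tuple(cs) for v, cs in payload["standardization"].items()},
            trace=payload.get("trace", []),
            status=payload.get("status", "ok"),
            n=payload.get("n", 0),
            n_events=payload.get("n_events", 0),
        )


def forward_select_bic(cohort: CohortTable, screened, force=()) -> RiskScoreResults:
    """Greedy BIC forward selection over an already-screened variable set
    (the screen stage is bypassed: every member of ``screened`` is eligible)."""
    model = RiskScoreModel(cohort, candidates=list(screened), force=force,
                           screen_threshold=1.1)  # p < 1.1 always: keep all
    return model.fit()


def compute_risk_score(results: RiskScoreResults, cohort: CohortTable) -> pd.Series:
    """Functional wrapper around :meth:`RiskScoreResults.predict`."""
    return results.predict(cohort)
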