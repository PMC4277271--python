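"""In-hospital survival: Kaplan-Meier, log-rank and Cox proportional hazards.

Death in hospital is the event; discharge alive is right-censoring at the
discharge time. The Kaplan-Meier product-limit estimator and the two-group
log-rank test come from :mod:`lifelines`; Cox models maximize the Breslow
partial likelihood via :class:`statsmodels` ``PHReg`` followed by a Newton
polish to a strict score tolerance (max |score| < 1e-8), so the reported
convergence flag has a precise meaning. Confidence intervals are normal
approximations on the log-hazard scale with z = 1.96.

Clinical reports in this literature often label Cox hazard-ratio estimates
"OR"; the fields here are named ``hr`` and should be read as hazard ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from statsmodels.duration.hazard_regression import PHReg

from .classify import CRITERIA, ClassificationTable
from .cohort import Cohort, IntegrityError
from .concordance import discordant_sets, pct

__all__ = [
    "Z_95",
    "DEFAULT_ADJUSTMENT",
    "SingularInformationError",
    "KMCurve",
    "CoxFit",
    "km_estimate",
    "logrank",
    "cox_fit",
    "survival_frame",
    "mortality_table",
    "survival_report",
    "km_curves_frame",
]

Z_95 = 1.96

#: Covariates of the adjusted in-hospital mortality models.
DEFAULT_ADJUSTMENT = [
    "male",
    "age_years",
    "hemoglobin_g_L",
    "albumin_g_L",
    "acei_arb",
    "diuretic",
]


class SingularInformationError(Exception):
    """The observed information matrix is singular (collinear covariates)."""


@dataclass
class KMCurve:
    """Product-limit survival curve evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(np.diff(self.survival) > 1e-12) or (
            self.survival.size and self.survival[0] > 1 + 1e-12
        ):
            raise ValueError("survival must be non-increasing and start <= 1")

    def at(self, t: float) -> float:
        """S(t): survival just after time t."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


@dataclass
class CoxFit:
    """Breslow Cox partial-likelihood fit."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n: int
    n_events: int
    converged: bool
    n_dropped_missing: int = 0

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci95(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.exp(self.coef - Z_95 * self.se),
            np.exp(self.coef + Z_95 * self.se),
        )

    def summary(self) -> pd.DataFrame:
        lo, hi = self.ci95
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "hr": self.hr,
                "ci95_low": lo,
                "ci95_high": hi,
            },
            index=pd.Index(self.names, name="covariate"),
        )

    def to_dict(self) -> dict:
        lo, hi = self.ci95
        return {
            "n": self.n,
            "n_events": self.n_events,
            "n_dropped_missing": self.n_dropped_missing,
            "converged": self.converged,
            "loglik": self.loglik,
            "terms": {
                name: {
                    "coef": float(c),
                    "se": float(s),
                    "hr": float(np.exp(c)),
                    "ci95": [float(l), float(h)],
                }
                for name, c, s, l, h in zip(self.names, self.coef, self.se, lo, hi)
            },
        }


def km_estimate(data: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier estimate from a frame with ``time`` and ``event`` columns.

    Subjects censored exactly at an event time count as at risk at that time
    (the standard convention).
    """
    if len(data) == 0:
        raise ValueError("no subjects")
    kmf = KaplanMeierFitter()
    kmf.fit(data["time"], event_observed=data["event"].astype(int))
    tab = kmf.event_table
    tab = tab[tab["observed"] > 0]
    times = tab.index.to_numpy(dtype=float)
    surv = np.array([kmf.survival_function_at_times(t).iloc[0] for t in times])
    return KMCurve(
        event_times=times,
        survival=surv,
        at_risk=tab["at_risk"].to_numpy(dtype=int),
        deaths=tab["observed"].to_numpy(dtype=int),
    )


def logrank(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p)."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    if int(group_a["event"].sum()) + int(group_b["event"].sum()) == 0:
        raise ValueError("log-rank statistic undefined with zero events")
    res = logrank_test(
        group_a["time"], group_b["time"],
        event_observed_A=group_a["event"].astype(int),
        event_observed_B=group_b["event"].astype(int),
    )
    return float(res.test_statistic), float(res.p_value)


def _newton_polish(
    model: PHReg, beta: np.ndarray, score_tol: float = 1e-8, max_iter: int = 50
) -> tuple[np.ndarray, bool]:
    """Newton-Raphson refinement to a strict score tolerance."""
    prev_ll = model.loglike(beta)
    for _ in range(max_iter):
        g = model.score(beta)
        if np.max(np.abs(g)) < score_tol:
            return beta, True
        h = model.hessian(beta)
        try:
            step = np.linalg.solve(h, g)
        except np.linalg.LinAlgError as exc:
            raise SingularInformationError(str(exc)) from exc
        candidate = beta - step
        if np.max(np.abs(candidate)) > 20:
            return candidate, False  # runaway estimate: monotone likelihood
        ll = model.loglike(candidate)
        # damped steps if the full Newton step overshoots
        shrink = 0
        while not np.isfinite(ll) or ll < prev_ll - 1e-10:
            step /= 2.0
            candidate = beta - step
            ll = model.loglike(candidate)
            shrink += 1
            if shrink > 30:
                return beta, False
        if abs(ll - prev_ll) < 1e-10 * max(1.0, abs(prev_ll)):
            beta = candidate
            g = model.score(beta)
            return beta, bool(np.max(np.abs(g)) < 1e-6)
        beta, prev_ll = candidate, ll
    return beta, bool(np.max(np.abs(model.score(beta))) < 1e-6)


def cox_fit(
    data: pd.DataFrame,
    covariates: Sequence[str],
    ties: str = "breslow",
) -> CoxFit:
    """Fit a Cox proportional-hazards model.

    Parameters
    ----------
    data
        Frame with ``time`` (> 0), ``event`` (0/1) and covariate columns.
        Rows with missing covariates are dropped (complete-case) and counted
        in ``n_dropped_missing``.
    covariates
        Names of the model terms; none may be constant after row dropping.
    ties
        Partial-likelihood tie handling, ``"breslow"`` or ``"efron"``.

    Raises
    ------
    SingularInformationError
        for collinear covariates (e.g. a duplicated column).
    ValueError
        for constant covariates or fewer events than parameters.
    """
    covariates = list(covariates)
    cols = ["time", "event", *covariates]
    frame = data[cols].copy()
    n_before = len(frame)
    frame = frame.dropna()
    n_dropped = n_before - len(frame)
    y = frame["time"].to_numpy(dtype=float)
    status = frame["event"].to_numpy(dtype=int)
    X = frame[covariates].to_numpy(dtype=float)
    n_events = int(status.sum())
    if n_events < len(covariates):
        raise ValueError(
            f"{n_events} events cannot support {len(covariates)} covariates"
        )
    if np.any(X.std(axis=0) == 0):
        constant = [c for c, s in zip(covariates, X.std(axis=0)) if s == 0]
        raise ValueError(f"constant covariate(s): {constant}")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        raise SingularInformationError(f"collinear covariates among {covariates}")

    model = PHReg(y, X, status=status, ties=ties)
    # collinearity was ruled out above, so an optimizer failure here means a
    # badly conditioned likelihood (e.g. separation): restart from zero and
    # let the damped Newton polish either converge or flag the fit
    try:
        with warnings.catch_warnings():
            # convergence is re-assessed by the Newton polish below
            warnings.simplefilter("ignore")
            start = np.asarray(model.fit(disp=False).params, dtype=float)
        if not np.all(np.isfinite(start)):
            start = np.zeros(X.shape[1])
    except (np.linalg.LinAlgError, ValueError):
        start = np.zeros(X.shape[1])
    beta, converged = _newton_polish(model, start)
    if np.max(np.abs(beta)) > 15:
        converged = False  # monotone likelihood / separation
    try:
        info = -model.hessian(beta)
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError as exc:
        if converged:
            raise SingularInformationError(str(exc)) from exc
        se = np.full(X.shape[1], np.nan)  # rejected fit; no usable information
    return CoxFit(
        names=covariates,
        coef=beta,
        se=se,
        loglik=float(model.loglike(beta)),
        n=len(frame),
        n_events=n_events,
        converged=converged,
        n_dropped_missing=n_dropped,
    )


# ---------------------------------------------------------------------------
# Cohort-level assembly
# ---------------------------------------------------------------------------


def survival_frame(cohort: Cohort) -> pd.DataFrame:
    """Per-subject survival input: time, event and adjustment covariates."""
    rows = []
    for p in cohort:
        rows.append(
            {
                "patient_id": p.patient_id,
                "time": p.outcome_time_hours,
                "event": int(p.died_in_hospital),
                "male": int(p.sex == "male"),
                "age_years": p.age_years,
                "hemoglobin_g_L": p.hemoglobin_g_L,
                "albumin_g_L": p.albumin_g_L,
                "acei_arb": int(p.acei_arb),
                "diuretic": int(p.diuretic),
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")


def mortality_table(table: ClassificationTable, cohort: Cohort) -> pd.DataFrame:
    """Death counts and percentages by criterion, overall and per stage.

    Includes the discordant-union group. Raises if a classified patient has
    no outcome record.
    """
    outcomes = {p.patient_id: p.died_in_hospital for p in cohort}
    missing = [pid for pid in table.rows if pid not in outcomes]
    if missing:
        raise IntegrityError(f"no outcome for patient(s): {missing[:5]}")
    records = []

    def add(criterion: str, group: str, pids: list[str]) -> None:
        deaths = sum(outcomes[pid] for pid in pids)
        records.append(
            {
                "criterion": criterion,
                "group": group,
                "n": len(pids),
                "deaths": int(deaths),
                "mortality_pct": pct(int(deaths), len(pids)) if pids else float("nan"),
            }
        )

    for criterion in CRITERIA:
        stages = {pid: row.get(criterion).stage for pid, row in table.rows.items()}
        add(criterion, "aki", [pid for pid, s in stages.items() if s >= 1])
        add(criterion, "no_aki", [pid for pid, s in stages.items() if s == 0])
        for s in (1, 2, 3):
            add(criterion, f"stage_{s}", [pid for pid, st in stages.items() if st == s])

    sets = discordant_sets(table)
    union = sorted(sets["union"])
    kdigo_stage = {pid: row.kdigo.stage for pid, row in table.rows.items()}
    add("K(+)R(-)+K(+)A(-)", "aki", union)
    add(
        "K(+)R(-)+K(+)A(-)",
        "no_aki",
        [pid for pid, row in table.rows.items() if not row.kdigo.detected],
    )
    for s in (1, 2, 3):
        add(
            "K(+)R(-)+K(+)A(-)",
            f"stage_{s}",
            [pid for pid in union if kdigo_stage[pid] == s],
        )
    return pd.DataFrame.from_records(records)


def _fit_or_flag(df: pd.DataFrame, covariates: list[str]) -> dict:
    try:
        fit = cox_fit(df, covariates)
    except (ValueError, SingularInformationError) as exc:
        return {"error": str(exc)}
    return fit.to_dict()


def survival_report(
    cohort: Cohort,
    table: ClassificationTable,
    adjustment: Sequence[str] = tuple(DEFAULT_ADJUSTMENT),
) -> dict:
    """Unadjusted and adjusted Cox models for each AKI definition.

    Four model families are fitted: RIFLE, AKIN and KDIGO (binary AKI and
    per-stage indicators, on the full cohort) and the discordant union
    (binary indicator, on the subcohort of KDIGO-negative patients plus the
    union group). Each family also carries its log-rank test against the
    corresponding no-AKI group.
    """
    adjustment = list(adjustment)
    base = survival_frame(cohort)
    sets = discordant_sets(table)
    report: dict = {
        "conventions": {
            "event": "in-hospital death; discharge alive treated as right-censoring",
            "ties": "breslow",
            "estimates": "hazard ratios (reported as 'OR' in parts of the clinical literature)",
            "missing_covariates": "complete-case within each adjusted model",
            "adjustment": adjustment,
        },
        "models": {},
    }

    def family(name: str, df: pd.DataFrame, terms: list[str]) -> dict:
        out = {
            "unadjusted": _fit_or_flag(df, terms),
            "adjusted": _fit_or_flag(df, terms + adjustment),
        }
        return out

    for criterion in CRITERIA:
        stages = {pid: row.get(criterion).stage for pid, row in table.rows.items()}
        df = base.copy()
        df["aki"] = [int(stages[pid] >= 1) for pid in df.index]
        for s in (1, 2, 3):
            df[f"stage_{s}"] = [int(stages[pid] == s) for pid in df.index]
        fam = {
            "all_stages": family(criterion, df, ["aki"]),
            "by_stage": family(criterion, df, ["stage_1", "stage_2", "stage_3"]),
        }
        chi2, p = logrank(df[df["aki"] == 1], df[df["aki"] == 0])
        fam["logrank_vs_no_aki"] = {"chi_square": chi2, "p": p}
        report["models"][criterion] = fam

    union = sets["union"]
    kdigo_neg = {pid for pid, row in table.rows.items() if not row.kdigo.detected}
    sub = base.loc[[pid for pid in base.index if pid in union | kdigo_neg]].copy()
    sub["aki"] = [int(pid in union) for pid in sub.index]
    fam = {"all_stages": family("discordant_union", sub, ["aki"])}
    chi2, p = logrank(sub[sub["aki"] == 1], sub[sub["aki"] == 0])
    fam["logrank_vs_no_aki"] = {"chi_square": chi2, "p": p}
    fam["subcohort"] = {"n": len(sub), "n_union": len(union), "n_no_aki": len(kdigo_neg)}
    report["models"]["K(+)R(-)+K(+)A(-)"] = fam
    return report


def km_curves_frame(cohort: Cohort, table: ClassificationTable) -> pd.DataFrame:
    """Long-format KM curves per definition and AKI status (for plotting)."""
    base = survival_frame(cohort)
    sets = discordant_sets(table)
    rows = []

    def emit(group: str, df: pd.DataFrame) -> None:
        if len(df) == 0 or df["event"].sum() == 0:
            return
        curve = km_estimate(df)
        for t, s, r in zip(curve.event_times, curve.survival, curve.at_risk):
            rows.append({"group": group, "time": t, "survival": s, "at_risk": r})

    for criterion in CRITERIA:
        detected = {pid for pid, row in table.rows.items() if row.get(criterion).detected}
        emit(f"{criterion}_aki", base.loc[base.index.isin(detected)])
        emit(f"{criterion}_no_aki", base.loc[~base.index.isin(detected)])
    union = sets["union"]
    kdigo_neg = {pid for pid, row in table.rows.items() if not row.kdigo.detected}
    emit("discordant_union", base.loc[base.index.isin(union)])
    emit("discordant_union_no_aki", base.loc[base.index.isin(kdigo_neg)])
    return pd.DataFrame(rows)
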