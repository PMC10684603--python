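"""Outcome machinery for grading verification.

Overall survival is analyzed with Kaplan-Meier curves and the log-rank
test; nonrelapse mortality and relapse are competing events analyzed with
the Aalen-Johansen cumulative incidence estimator and Gray's test.  Grading
systems are compared through Cox proportional hazards models with Efron tie
handling (grading AIC = -2 log L + 2 p' with p' the number of grade
categories), Fine-Gray subdistribution regression, Harrell's concordance
index and time-dependent (cumulative-case / dynamic-control) AUROC with
inverse-probability-of-censoring weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import AalenJohansenFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_concordance
from scipy import stats

from gvhdgrading.cohort import CohortTable, EVENT_CODES

EVENT_CODE_OF_INTEREST = {"nrm": 1, "relapse": 2}


@dataclass
class SurvivalCurve:
    """A step-function survival or cumulative-incidence estimate with
    pointwise 95% bands and at-risk counts."""

    times: np.ndarray
    estimate: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray
    label: Optional[str] = None
    kind: str = "survival"

    def at(self, t: float) -> float:
        """Step-function value at time t (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0 if self.kind == "survival" else 0.0
        return float(self.estimate[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "estimate": self.estimate,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "at_risk": self.at_risk,
            }
        )


@dataclass
class CoxFit:
    """A fitted proportional-hazards (or subdistribution-hazards) model."""

    coefficients: pd.Series
    se: pd.Series
    loglik: float
    ties_method: str
    n_params: int
    n: int
    n_events: int
    model: str = "cox"

    @property
    def hazard_ratios(self) -> pd.DataFrame:
        z = stats.norm.ppf(0.975)
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "hr": np.exp(self.coefficients),
                "hr_lower": np.exp(self.coefficients - z * self.se),
                "hr_upper": np.exp(self.coefficients + z * self.se),
                "p": 2 * stats.norm.sf(np.abs(self.coefficients / self.se)),
            }
        )


def _group_arrays(cohort: CohortTable, groups) -> np.ndarray:
    if groups is None:
        return np.zeros(len(cohort), dtype=object)
    groups = np.asarray(groups, dtype=object)
    if len(groups) != len(cohort):
        raise ValueError("group labels must match cohort length")
    return groups


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


def kaplan_meier(
    cohort: CohortTable, groups: Optional[Sequence] = None
) -> dict[object, SurvivalCurve]:
    """Product-limit overall-survival estimate per group with Greenwood
    95% bands on the log(-log) scale.  Groups with zero patients are
    omitted with a warning."""
    g = _group_arrays(cohort, groups)
    times, events = cohort.times, cohort.os_events
    out: dict[object, SurvivalCurve] = {}
    for label in pd.unique(g):
        mask = g == label
        if mask.sum() == 0:  # pragma: no cover - pd.unique never yields these
            warnings.warn(f"group {label!r} empty; omitted", stacklevel=2)
            continue
        kmf = KaplanMeierFitter().fit(times[mask], events[mask])
        sf = kmf.survival_function_
        ci = kmf.confidence_interval_survival_function_
        tab = kmf.event_table
        out[label] = SurvivalCurve(
            times=sf.index.to_numpy(dtype=float),
            estimate=sf.iloc[:, 0].to_numpy(),
            ci_lower=ci.iloc[:, 0].to_numpy(),
            ci_upper=ci.iloc[:, 1].to_numpy(),
            at_risk=tab["at_risk"].to_numpy(),
            label=str(label),
            kind="survival",
        )
    return out


def logrank_test(cohort: CohortTable, groups: Sequence) -> tuple[float, int, float]:
    """Unweighted K-sample log-rank test for overall survival.

    Returns (chi-square statistic, degrees of freedom, two-sided p).
    """
    g = _group_arrays(cohort, groups)
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ValueError("log-rank test needs at least 2 nonempty groups")
    res = multivariate_logrank_test(cohort.times, g, cohort.os_events)
    df = len(labels) - 1
    return float(res.test_statistic), df, float(res.p_value)


# ---------------------------------------------------------------------------
# Competing risks: Aalen-Johansen and Gray's test


def cumulative_incidence(
    cohort: CohortTable,
    event_of_interest: str = "nrm",
    groups: Optional[Sequence] = None,
) -> dict[object, SurvivalCurve]:
    """Aalen-Johansen cumulative incidence of one event type in the
    presence of the competing one, per group."""
    code = EVENT_CODE_OF_INTEREST[event_of_interest]
    g = _group_arrays(cohort, groups)
    times, codes = cohort.times, cohort.event_codes
    out: dict[object, SurvivalCurve] = {}
    for label in pd.unique(g):
        mask = g == label
        ajf = AalenJohansenFitter(calculate_variance=True, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tie-jitter notice
            ajf.fit(times[mask], codes[mask], event_of_interest=code)
        cif = ajf.cumulative_density_
        ci = ajf.confidence_interval_cumulative_density_
        tab = ajf.event_table
        out[label] = SurvivalCurve(
            times=cif.index.to_numpy(dtype=float),
            estimate=cif.iloc[:, 0].to_numpy(),
            ci_lower=ci.iloc[:, 0].to_numpy(),
            ci_upper=ci.iloc[:, 1].to_numpy(),
            at_risk=tab["at_risk"].reindex(cif.index).to_numpy(),
            label=str(label),
            kind="cif",
        )
    return out


class _StepFunction:
    """Right-continuous step function with left-limit evaluation."""

    def __init__(self, times: np.ndarray, values: np.ndarray, start: float = 1.0):
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.start = start

    def __call__(self, t) -> np.ndarray:
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], self.start)
        return out

    def left(self, t) -> np.ndarray:
        idx = np.searchsorted(self.times, t, side="left") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], self.start)
        return out


def _censoring_survival(times: np.ndarray, codes: np.ndarray) -> _StepFunction:
    """Kaplan-Meier of the censoring distribution (censoring as the event)."""
    kmf = KaplanMeierFitter().fit(times, (codes == 0).astype(int))
    sf = kmf.survival_function_
    return _StepFunction(sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy())


def gray_test(
    cohort: CohortTable,
    event_of_interest: str = "nrm",
    groups: Sequence = None,
) -> tuple[float, int, float]:
    """Gray's K-sample test (rho = 0) for equality of cumulative incidence
    functions, chi-square reference with K-1 degrees of freedom.

    Implemented as the score-form subdistribution log-rank: subjects who
    failed from the competing cause remain in the risk set with
    inverse-probability-of-censoring weights G(t-)/G(T_i-), the Fine-Gray
    risk-set construction.  With no censoring this is exactly the log-rank
    test applied to the subdistribution times.
    """
    code = EVENT_CODE_OF_INTEREST[event_of_interest]
    g = _group_arrays(cohort, groups)
    labels = list(pd.unique(g))
    if len(labels) < 2:
        raise ValueError("Gray's test needs at least 2 nonempty groups")
    K = len(labels)
    group_idx = np.asarray([labels.index(x) for x in g])
    T, codes = cohort.times, cohort.event_codes
    G = _censoring_survival(T, codes)
    GmT = np.maximum(G.left(T), 1e-12)  # G(T_i-) per subject

    is_interest = codes == code
    is_competing = (codes != 0) & (codes != code)
    event_times = np.unique(T[is_interest])

    z = np.zeros(K)
    V = np.zeros((K, K))
    for t in event_times:
        Gm_t = float(G.left(t))
        w = (T >= t).astype(float)
        late = is_competing & (T < t)
        w[late] = Gm_t / GmT[late]
        Ystar = np.bincount(group_idx, weights=w, minlength=K)
        Ytot = Ystar.sum()
        if Ytot <= 0:
            continue
        d_k = np.bincount(
            group_idx[is_interest & (T == t)], minlength=K
        ).astype(float)
        d = d_k.sum()
        p = Ystar / Ytot
        z += d_k - d * p
        if Ytot > 1:
            mult = d * (Ytot - d) / (Ytot - 1)
            V += mult * (np.diag(p) - np.outer(p, p))
    zr, Vr = z[:-1], V[:-1, :-1]
    if np.allclose(zr, 0) and np.allclose(Vr, 0):
        return 0.0, K - 1, 1.0
    statistic = float(zr @ np.linalg.pinv(Vr) @ zr)
    statistic = max(statistic, 0.0)
    p_value = float(stats.chi2.sf(statistic, K - 1))
    return statistic, K - 1, p_value


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties, optional start-stop intervals)


class ConvergenceError(RuntimeError):
    """Partial-likelihood maximization failed to converge."""


def _as_design(covariates, cohort: Optional[CohortTable]) -> pd.DataFrame:
    if isinstance(covariates, pd.DataFrame):
        return covariates.reset_index(drop=True).astype(float)
    if isinstance(covariates, (list, tuple)) and all(
        isinstance(c, str) for c in covariates
    ):
        if cohort is None:
            raise ValueError("column names need a cohort to resolve against")
        return cohort.df[list(covariates)].reset_index(drop=True).astype(float)
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])


def cox_fit(
    cohort: Optional[CohortTable],
    covariates,
    intervals: Optional[pd.DataFrame] = None,
    ties: str = "efron",
    outcome: str = "os",
) -> CoxFit:
    """Cox proportional hazards fit by partial-likelihood maximization.

    ``ties`` selects the Efron (default) or Breslow tie correction; on
    tie-free data the two likelihoods coincide.  ``intervals`` accepts a
    counting-process DataFrame with columns ``start``, ``stop``, ``event``
    and covariate columns, enabling time-dependent covariates such as a
    grade entering at aGVHD onset.  ``outcome='nrm'`` fits the
    cause-specific hazard of nonrelapse death (relapse treated as
    censoring).
    """
    from statsmodels.duration.hazard_regression import PHReg

    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    if intervals is not None:
        cov_cols = [
            c for c in intervals.columns if c not in ("start", "stop", "event")
        ]
        X = intervals[cov_cols].astype(float)
        endog = intervals["stop"].to_numpy(dtype=float)
        status = intervals["event"].to_numpy(dtype=int)
        entry = intervals["start"].to_numpy(dtype=float)
    else:
        X = _as_design(covariates, cohort)
        endog = cohort.times
        if outcome == "os":
            status = cohort.os_events
        elif outcome == "nrm":
            status = (cohort.event_codes == 1).astype(int)
        else:
            raise ValueError("outcome must be 'os' or 'nrm'")
        entry = None
    if status.sum() == 0:
        raise ValueError("no events observed; Cox model undefined")
    model = PHReg(endog, X.to_numpy(), status=status, entry=entry, ties=ties)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=200)
    score = model.score(res.params)
    gnorm = float(np.linalg.norm(score))
    if not np.all(np.isfinite(res.params)) or gnorm > 1e-3 * max(1, status.sum()):
        raise ConvergenceError(
            f"Cox partial likelihood did not converge (gradient norm {gnorm:.3g})"
        )
    names = list(X.columns)
    return CoxFit(
        coefficients=pd.Series(res.params, index=names),
        se=pd.Series(res.bse, index=names),
        loglik=float(model.loglike(res.params)),
        ties_method=ties,
        n_params=len(names),
        n=len(X),
        n_events=int(status.sum()),
    )


# ---------------------------------------------------------------------------
# Fine-Gray subdistribution regression


def finegray_expand(
    cohort: CohortTable, event_of_interest: str = "nrm"
) -> pd.DataFrame:
    """Expand a competing-risks cohort into weighted counting-process rows
    for the Fine-Gray model.

    Subjects failing from the competing cause stay in the risk set past
    their failure time with weight G(t-)/G(T_i-), split into intervals at
    the event-of-interest times; everyone else contributes one unit-weight
    row.
    """
    code = EVENT_CODE_OF_INTEREST[event_of_interest]
    T, codes = cohort.times, cohort.event_codes
    G = _censoring_survival(T, codes)
    interest_times = np.unique(T[codes == code])
    rows = []
    for i in range(len(T)):
        if codes[i] == code or codes[i] == 0:
            rows.append((i, 0.0, T[i], int(codes[i] == code), 1.0))
        else:
            rows.append((i, 0.0, T[i], 0, 1.0))
            g_at_fail = max(float(G.left(T[i])), 1e-12)
            later = interest_times[interest_times > T[i]]
            start = T[i]
            for t in later:
                w = float(G.left(t)) / g_at_fail
                if w <= 0:
                    break
                rows.append((i, start, t, 0, w))
                start = t
    out = pd.DataFrame(
        rows, columns=["subject", "start", "stop", "event", "weight"]
    )
    return out[out["stop"] > out["start"]].reset_index(drop=True)


def fine_gray_fit(
    cohort: CohortTable, covariates, event_of_interest: str = "nrm"
) -> CoxFit:
    """Fine-Gray subdistribution-hazard regression for one event type.

    Baseline (static) covariates only.  With no competing events present
    the expansion is trivial and the fit equals the cause-specific Cox fit.
    """
    from lifelines import CoxTimeVaryingFitter

    X = _as_design(covariates, cohort)
    expanded = finegray_expand(cohort, event_of_interest)
    data = expanded.join(X, on="subject")
    ctv = CoxTimeVaryingFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ctv.fit(
            data.drop(columns=["subject"]),
            start_col="start",
            stop_col="stop",
            event_col="event",
            weights_col="weight",
        )
    return CoxFit(
        coefficients=ctv.params_.copy(),
        se=ctv.standard_errors_.copy(),
        loglik=float(ctv.log_likelihood_),
        ties_method="efron",
        n_params=len(ctv.params_),
        n=len(cohort),
        n_events=int(expanded["event"].sum()),
        model="fine-gray",
    )


# ---------------------------------------------------------------------------
# Grading comparison metrics


def grading_aic(
    cohort: CohortTable,
    grades: Sequence,
    p_convention: str = "categories",
    outcome: str = "os",
    ties: str = "efron",
) -> float:
    """Grading AIC = -2 log L + 2 p'.

    L is the Cox partial likelihood (Efron ties) with the grade as a dummy-
    encoded covariate; p' is, by convention here, the number of grade
    categories (set ``p_convention='parameters'`` for the usual
    categories-minus-one count).  Smaller is better.
    """
    grades = pd.Series(list(grades), dtype="category")
    n_categories = len(grades.cat.categories)
    if n_categories < 2:
        raise ValueError("grading AIC needs at least 2 grade categories")
    dummies = pd.get_dummies(grades, drop_first=True, dtype=float)
    fit = cox_fit(cohort, dummies, ties=ties, outcome=outcome)
    if p_convention == "categories":
        p_prime = n_categories
    elif p_convention == "parameters":
        p_prime = n_categories - 1
    else:
        raise ValueError("p_convention must be 'categories' or 'parameters'")
    return -2.0 * fit.loglik + 2.0 * p_prime


def harrell_c(cohort: CohortTable, scores: Sequence, outcome: str = "os") -> float:
    """Harrell's concordance index for a risk score (higher score = higher
    risk).  Tied scores count 0.5; pairs unusable under censoring are
    excluded.  Returns NaN with a warning when no usable pairs exist."""
    scores = np.asarray(scores, dtype=float)
    if outcome == "os":
        events = cohort.os_events
    elif outcome == "nrm":
        events = (cohort.event_codes == 1).astype(int)
    else:
        raise ValueError("outcome must be 'os' or 'nrm'")
    try:
        # lifelines expects higher prediction = longer survival
        return float(_lifelines_concordance(cohort.times, -scores, events))
    except ZeroDivisionError:
        warnings.warn("no usable pairs; concordance undefined", stacklevel=2)
        return float("nan")


def td_auroc(
    cohort: CohortTable,
    scores: Sequence,
    horizon: float = 365.0,
    outcome: str = "os",
    n_bootstrap: int = 200,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Time-dependent AUROC at a horizon (cumulative cases, dynamic
    controls) with Kaplan-Meier inverse-probability-of-censoring weights;
    95% CI from seeded bootstrap resampling.

    For ``outcome='nrm'`` the cause-specific event is used (relapse treated
    as censoring).  Returns (NaN, (NaN, NaN)) with a warning when there are
    no cases or no controls at the horizon.
    """
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    scores = np.asarray(scores, dtype=float)
    T = cohort.times
    if outcome == "os":
        events = cohort.os_events.astype(bool)
    elif outcome == "nrm":
        events = cohort.event_codes == 1
    else:
        raise ValueError("outcome must be 'os' or 'nrm'")
    if horizon >= T.max():
        raise ValueError("horizon must lie within follow-up")

    def _auc(idx: np.ndarray) -> float:
        t, e, s = T[idx], events[idx], scores[idx]
        cases = e & (t <= horizon)
        controls = t > horizon
        if cases.sum() == 0 or controls.sum() == 0:
            return float("nan")
        y = Surv.from_arrays(event=e, time=t)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            auc, _ = cumulative_dynamic_auc(y, y, s, [horizon])
        return float(auc[0])

    point = _auc(np.arange(len(T)))
    if np.isnan(point):
        warnings.warn(
            "no cases or no controls at the horizon; AUROC undefined",
            stacklevel=2,
        )
        return point, (float("nan"), float("nan"))
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, len(T), size=len(T))
        try:
            value = _auc(idx)
        except ValueError:
            continue
        if np.isfinite(value):
            reps.append(value)
    if len(reps) >= 10:
        lo, hi = np.percentile(reps, [2.5, 97.5])
    else:
        lo = hi = float("nan")
    return point, (float(lo), float(hi))
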