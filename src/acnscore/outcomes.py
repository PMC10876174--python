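"""Outcome-association machinery for score comparison.

Kaplan-Meier estimation and the log-rank test (via lifelines), Cox
proportional-hazards fits with Breslow tie handling (via statsmodels
``PHReg``; Efron available), and logistic regression with ROC AUC (via
statsmodels), all reported with AIC = 2k - 2 log L so that the four
diagnostic scores can be ranked by the information criterion, lowest
being best.  Class-labelled predictors are one-hot encoded against a
reference level (the most benign class).

Event coding: survival analyses default to event = died of disease
(DOD), censoring CR and AWD at last follow-up; the logistic outcome
defaults to the composite unfavorable = AWD or DOD vs CR.  Both are
configurable because published score-validation studies rarely state the
coding explicitly.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Hashable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import rankdata

from .cohort import Outcome


class EventDefinition(enum.Enum):
    DOD = "dod"                # death of disease is the event
    AWD_OR_DOD = "awd_or_dod"  # composite unfavorable outcome


def outcome_event(outcome: Outcome, definition: EventDefinition) -> Optional[bool]:
    """Map an outcome category to an event indicator (None if unknown)."""
    if outcome is Outcome.UNKNOWN:
        return None
    if definition is EventDefinition.DOD:
        return outcome is Outcome.DOD
    return outcome in (Outcome.DOD, Outcome.AWD)


@dataclass(frozen=True)
class SurvivalSample:
    time: float
    event: bool
    group: Hashable

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be positive")


class InsufficientDataError(ValueError):
    pass


class UndefinedTestError(ValueError):
    pass


@dataclass
class KMCurve:
    """Product-limit estimate: step times, survival values, at-risk counts."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    group: Optional[Hashable] = None


def km_estimate(samples: Sequence[SurvivalSample],
                by_group: bool = False) -> "KMCurve | dict":
    """Kaplan-Meier product-limit estimate, optionally per group.

    Censored times reduce the risk set without introducing steps.
    """
    if len(samples) == 0:
        raise InsufficientDataError("no survival samples")
    if by_group:
        groups = sorted({s.group for s in samples}, key=str)
        return {g: km_estimate([s for s in samples if s.group == g])
                for g in groups}
    times = np.array([s.time for s in samples], dtype=float)
    events = np.array([s.event for s in samples], dtype=bool)
    fitter = KaplanMeierFitter()
    fitter.fit(times, event_observed=events)
    grid = np.unique(times)
    surv = fitter.survival_function_at_times(grid).to_numpy(dtype=float)
    at_risk = np.array([(times >= t).sum() for t in grid], dtype=int)
    return KMCurve(times=grid, survival=surv, at_risk=at_risk,
                   group=samples[0].group if len({s.group for s in samples}) == 1 else None)


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p: float


def log_rank(samples: Sequence[SurvivalSample]) -> LogRankResult:
    """Standard (unweighted) log-rank test across the sample's groups."""
    groups = sorted({s.group for s in samples}, key=str)
    if len(groups) < 2:
        raise InsufficientDataError("log-rank needs at least two groups")
    if not any(s.event for s in samples):
        raise UndefinedTestError("log-rank undefined with no events")
    result = multivariate_logrank_test(
        np.array([s.time for s in samples], dtype=float),
        np.array([str(s.group) for s in samples]),
        np.array([s.event for s in samples], dtype=bool),
    )
    return LogRankResult(chi2=float(result.test_statistic),
                         df=len(groups) - 1,
                         p=float(result.p_value))


def _one_hot(labels: Sequence[Hashable],
             reference: Optional[Hashable] = None) -> tuple[np.ndarray, list]:
    """Dummy-code labels against a reference level (dropped column)."""
    levels = []
    for label in labels:
        if label not in levels:
            levels.append(label)
    if reference is None:
        reference = levels[0]
    elif reference not in levels:
        raise ValueError(f"reference level {reference!r} not observed")
    coded_levels = [lv for lv in levels if lv != reference]
    X = np.zeros((len(labels), len(coded_levels)))
    for i, label in enumerate(labels):
        if label != reference:
            X[i, coded_levels.index(label)] = 1.0
    return X, coded_levels


@dataclass
class CoxResult:
    params: dict
    se: dict
    log_partial_likelihood: float
    aic: float
    converged: bool
    n: int
    n_events: int
    ties: str = "breslow"

    @property
    def hazard_ratios(self) -> dict:
        return {k: float(np.exp(v)) for k, v in self.params.items()}

    def confint(self, name: str, level: float = 0.95) -> tuple[float, float]:
        """Wald confidence interval for one coefficient."""
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2)
        beta, se = self.params[name], self.se[name]
        return beta - z * se, beta + z * se


def cox_fit(samples: Sequence[SurvivalSample],
            reference: Optional[Hashable] = None,
            ties: str = "breslow") -> CoxResult:
    """Cox proportional-hazards fit on a class-labelled covariate.

    Ties are handled by the Breslow approximation by default ("efron"
    available).  Monotone likelihood (all events in one covariate
    pattern) is reported as a flagged non-converged result rather than
    an exception: the partial likelihood approaches a finite supremum,
    so the returned AIC is still usable for qualitative comparison.
    """
    if not any(s.event for s in samples):
        raise InsufficientDataError("Cox fit needs at least one event")
    labels = [s.group for s in samples]
    if len(set(labels)) < 2:
        raise InsufficientDataError("covariate is constant")
    X, coded = _one_hot(labels, reference)
    time = np.array([s.time for s in samples], dtype=float)
    status = np.array([s.event for s in samples], dtype=float)
    model = sm.PHReg(time, X, status=status, ties=ties)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(maxiter=200, disp=False)
            params = np.asarray(res.params, dtype=float)
            bse = np.asarray(res.bse, dtype=float)
        except Exception:
            converged = False
            params = np.zeros(X.shape[1])
            bse = np.full(X.shape[1], np.nan)
    if converged and (not np.all(np.isfinite(params)) or np.abs(params).max() > 15):
        converged = False
    llf = float(model.loglike(params))
    k = X.shape[1]
    names = [f"group[{lv}]" for lv in coded]
    return CoxResult(
        params=dict(zip(names, (float(b) for b in params))),
        se=dict(zip(names, (float(s) for s in bse))),
        log_partial_likelihood=llf,
        aic=2.0 * k - 2.0 * llf,
        converged=converged,
        n=len(samples),
        n_events=int(status.sum()),
        ties=ties,
    )


def mann_whitney_auc(scores: np.ndarray, outcomes: np.ndarray) -> float:
    """AUC as the Mann-Whitney statistic with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=bool)
    n_pos = int(outcomes.sum())
    n_neg = int((~outcomes).sum())
    if n_pos == 0 or n_neg == 0:
        raise InsufficientDataError("both outcome classes must be present")
    ranks = rankdata(scores)
    return float((ranks[outcomes].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class LogisticResult:
    params: dict
    log_likelihood: float
    aic: float
    auc: float
    converged: bool
    n: int


def logistic_fit(outcomes: Sequence[bool],
                 predictor: Sequence[Hashable],
                 reference: Optional[Hashable] = None) -> LogisticResult:
    """Maximum-likelihood logistic regression of a binary outcome on a
    one-hot-encoded class predictor, with ROC AUC of fitted probabilities.

    Complete separation is reported as a flagged result, not a crash.
    """
    y = np.array(outcomes, dtype=float)
    if y.min() == y.max():
        raise InsufficientDataError("outcome is constant")
    X, coded = _one_hot(list(predictor), reference)
    design = sm.add_constant(X, has_constant="add")
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
            params = np.asarray(res.params, dtype=float)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=200)
            params = np.asarray(res.params, dtype=float)
            converged = False
    if converged and np.abs(params).max() > 15:
        converged = False
    llf = float(res.llf)
    k = design.shape[1]
    from scipy.special import expit
    fitted = expit(design @ params)
    names = ["intercept"] + [f"group[{lv}]" for lv in coded]
    return LogisticResult(
        params=dict(zip(names, (float(b) for b in params))),
        log_likelihood=llf,
        aic=2.0 * k - 2.0 * llf,
        auc=mann_whitney_auc(fitted, y.astype(bool)),
        converged=converged,
        n=len(y),
    )


# Reference (most benign) level per score system, used to anchor the
# one-hot coding so hazard/odds ratios read as "vs benign-like".
_REFERENCE_LEVEL = {
    "wc_class": "benign",
    "mwc_class": "favorable",
    "ara_class": "benign",
    "pra_class": "benign",
}


@dataclass
class SystemComparison:
    system: str
    cox_aic: float
    cox_converged: bool
    logistic_aic: float
    logistic_auc: float
    logistic_converged: bool
    log_rank_p: float
    n: int
    n_events: int


@dataclass
class ModelComparison:
    systems: dict = field(default_factory=dict)  # name -> SystemComparison
    ranking: list = field(default_factory=list)  # by cox_aic ascending
    n_common: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [vars(self.systems[name]) for name in self.ranking]
        return pd.DataFrame(rows)


def compare_scores(panel: pd.DataFrame,
                   systems: Sequence[str] = ("wc_class", "mwc_class",
                                             "ara_class", "pra_class"),
                   survival_event: EventDefinition = EventDefinition.DOD,
                   logistic_event: EventDefinition = EventDefinition.AWD_OR_DOD,
                   complete_case: bool = True,
                   min_cases: int = 20) -> ModelComparison:
    """Rank score systems by Cox AIC (with logistic AIC/AUC and log-rank p).

    ``panel`` is a tidy frame with one row per case carrying the class
    columns named in ``systems`` plus ``outcome`` and ``followup_months``
    (as produced by :func:`acnscore.scoring.panel_frame`).  With
    ``complete_case`` (default) every system is evaluated on the
    identical subset of cases where all compared systems and the outcome
    are known, so the AICs are comparable.
    """
    systems = [s for s in systems if s in panel.columns]
    if len(systems) < 1:
        raise InsufficientDataError("no score systems present in the panel")
    df = panel.copy()
    df = df[df["outcome"].notna() & df["followup_months"].notna()
            & (df["followup_months"] > 0)]
    if complete_case:
        for s in systems:
            df = df[df[s].notna()]
    if len(df) < min_cases:
        raise InsufficientDataError(
            f"only {len(df)} usable cases (need >= {min_cases})")

    comparison = ModelComparison(n_common=len(df))
    for system in systems:
        sub = df if complete_case else df[df[system].notna()]
        outc = sub["outcome"].map(lambda v: Outcome(v))
        surv_event = outc.map(lambda o: outcome_event(o, survival_event))
        logi_event = outc.map(lambda o: outcome_event(o, logistic_event))
        samples = [SurvivalSample(t, bool(e), g) for t, e, g in
                   zip(sub["followup_months"], surv_event, sub[system])]
        ref = _REFERENCE_LEVEL.get(system)
        if ref is not None and ref not in set(sub[system]):
            ref = None
        cox = cox_fit(samples, reference=ref)
        logistic = logistic_fit(list(logi_event.astype(bool)),
                                list(sub[system]), reference=ref)
        try:
            lr = log_rank(samples)
            lr_p = lr.p
        except (InsufficientDataError, UndefinedTestError):
            lr_p = float("nan")
        comparison.systems[system] = SystemComparison(
            system=system, cox_aic=cox.aic, cox_converged=cox.converged,
            logistic_aic=logistic.aic, logistic_auc=logistic.auc,
            logistic_converged=logistic.converged, log_rank_p=lr_p,
            n=len(sub), n_events=cox.n_events,
        )
    comparison.ranking = sorted(
        comparison.systems, key=lambda s: comparison.systems[s].cox_aic)
    return comparison
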