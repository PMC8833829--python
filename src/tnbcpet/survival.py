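"""Survival analysis: Kaplan–Meier, log-rank, Cox models, horizon ROC/Youden.

Endpoints are right-censored time-to-event pairs in months (DFS: relapse;
OS: death). Cox models maximize the partial likelihood with Efron tie
handling and report Wald confidence intervals on the log-hazard scale.
Backward model selection drops, at each step, the covariate whose removal
lowers the AIC most, stopping when no removal helps.

Prognostic features are dichotomized through a fixed-horizon ROC: at the
horizon (default 24 months) subjects with an event at or before it are
positives, subjects event-free with follow-up past it are negatives, and
subjects censored earlier are excluded. A cutoff predicts positive when the
feature is >= cutoff; Youden's J = sensitivity + specificity - 1 picks the
operating point (ties to the lower cutoff).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines import statistics as lls
from lifelines.exceptions import ConvergenceError

from .imaging import ValidationError

__all__ = [
    "DiagnosticError",
    "KmCurve",
    "CoxResult",
    "RocCurve",
    "ThresholdResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "backward_aic",
    "roc_at_horizon",
    "youden_threshold",
    "compare_at_threshold",
    "ALPHA",
    "DEFAULT_HORIZON_MONTHS",
]

#: Two-sided significance level used throughout; no multiplicity adjustment.
ALPHA = 0.05

DEFAULT_HORIZON_MONTHS = 24.0


class DiagnosticError(RuntimeError):
    """A model could not be fit (no events, separation, non-convergence)."""


@dataclass(frozen=True)
class KmCurve:
    """Product-limit estimate; ``median`` is None when not reached."""

    times: np.ndarray
    survival: np.ndarray
    median: float | None
    n: int
    n_events: int


@dataclass(frozen=True)
class CoxResult:
    """Hazard ratios with 95% Wald CIs and p-values, plus fit summaries."""

    hr: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    p: dict[str, float]
    loglik: float
    aic: float
    covariates: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class RocCurve:
    """ROC points over all distinct cutoffs (predict positive at >= cutoff)."""

    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_positive: int
    n_negative: int
    n_excluded: int


@dataclass(frozen=True)
class ThresholdResult:
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float


def _as_arrays(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.shape != e.shape:
        raise ValidationError("time and event must have the same length")
    if np.any(t <= 0):
        raise ValidationError("survival times must be positive")
    if not np.isin(e, (0, 1)).all():
        raise ValidationError("event indicators must be 0/1")
    return t, e


def km_estimate(time, event) -> KmCurve:
    """Kaplan–Meier product-limit estimator with median survival.

    The median is the smallest t with S(t) <= 0.5; None when never reached.
    """
    t, e = _as_arrays(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    med = kmf.median_survival_time_
    median = None if math.isinf(med) else float(med)
    sf = kmf.survival_function_
    return KmCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        median=median,
        n=len(t),
        n_events=int(e.sum()),
    )


def logrank_test(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """One-degree-of-freedom log-rank test; returns (chi-square, p)."""
    ta, ea = _as_arrays(time_a, event_a)
    tb, eb = _as_arrays(time_b, event_b)
    res = lls.logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def _null_partial_loglik(time: np.ndarray, event: np.ndarray) -> float:
    """Efron partial log-likelihood of the covariate-free Cox model.

    With every risk score equal to one the Efron denominators at an event time
    with d ties and n at risk are n, n-1, ..., n-d+1.
    """
    ll = 0.0
    for t in np.unique(time[event == 1]):
        d = int(((time == t) & (event == 1)).sum())
        n_risk = int((time >= t).sum())
        ll -= sum(math.log(n_risk - l) for l in range(d))
    return ll


def cox_fit(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties) for the given covariates."""
    if not covariates:
        raise ValidationError("cox_fit needs at least one covariate")
    t, e = _as_arrays(data[duration_col], data[event_col])
    if e.sum() == 0:
        raise DiagnosticError("no events observed; Cox model is not identifiable")
    X = data[covariates].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("covariates must be finite")
    df = data[[duration_col, event_col, *covariates]].copy()
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        raise DiagnosticError(f"Cox fit failed to converge: {err}") from err
    summary = cph.summary
    hr = {c: float(summary.loc[c, "exp(coef)"]) for c in covariates}
    ci = {
        c: (
            float(summary.loc[c, "exp(coef) lower 95%"]),
            float(summary.loc[c, "exp(coef) upper 95%"]),
        )
        for c in covariates
    }
    p = {c: float(summary.loc[c, "p"]) for c in covariates}
    loglik = float(cph.log_likelihood_)
    return CoxResult(
        hr=hr,
        ci95=ci,
        p=p,
        loglik=loglik,
        aic=float(cph.AIC_partial_),
        covariates=tuple(covariates),
    )


def backward_aic(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    candidates: list[str],
) -> tuple[CoxResult | None, list[str]]:
    """Stepwise backward elimination on AIC from the full candidate model.

    At each step the covariate whose removal lowers the AIC most is dropped;
    the path stops when no single removal helps. Dropping the last covariate
    is allowed if the null model (AIC = -2 * null partial log-likelihood)
    wins, in which case the result is ``(None, [])``.
    """
    if not candidates:
        raise ValidationError("backward_aic needs at least one candidate covariate")
    t, e = _as_arrays(data[duration_col], data[event_col])
    null_aic = -2.0 * _null_partial_loglik(t, e)

    retained = list(candidates)
    current = cox_fit(data, duration_col, event_col, retained)
    while retained:
        options: list[tuple[float, list[str], CoxResult | None]] = []
        for drop in retained:
            rest = [c for c in retained if c != drop]
            if rest:
                fit = cox_fit(data, duration_col, event_col, rest)
                options.append((fit.aic, rest, fit))
            else:
                options.append((null_aic, [], None))
        best_aic, best_set, best_fit = min(options, key=lambda o: o[0])
        if current is not None and best_aic < current.aic:
            retained = best_set
            current = best_fit
            if current is None:
                break
        else:
            break
    return current, retained


def roc_at_horizon(
    time,
    event,
    feature,
    horizon: float = DEFAULT_HORIZON_MONTHS,
) -> RocCurve:
    """ROC for event-by-horizon classification from a continuous feature.

    Positives: event at or before the horizon. Negatives: event-free with
    follow-up reaching the horizon (events after the horizon count as
    negatives). Censored before the horizon without an event: excluded.
    """
    t, e = _as_arrays(time, event)
    f = np.asarray(feature, dtype=float)
    if f.shape != t.shape:
        raise ValidationError("feature must align with outcomes")
    positive = (e == 1) & (t <= horizon)
    negative = t >= horizon
    negative &= ~positive
    included = positive | negative
    n_pos, n_neg = int(positive.sum()), int(negative.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError(
            f"horizon ROC needs both classes; got {n_pos} positives, {n_neg} negatives"
        )
    fpos = np.sort(f[positive])
    fneg = np.sort(f[negative])
    cutoffs = np.unique(f[included])[::-1]
    # feature >= cutoff → positive prediction
    tp = n_pos - np.searchsorted(fpos, cutoffs, side="left")
    fp = n_neg - np.searchsorted(fneg, cutoffs, side="left")
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    fpr = np.concatenate([[0.0], fp / n_neg, [1.0]])
    tpr = np.concatenate([[0.0], sens, [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(
        cutoffs=cutoffs,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        n_positive=n_pos,
        n_negative=n_neg,
        n_excluded=int((~included).sum()),
    )


def youden_threshold(roc: RocCurve) -> ThresholdResult:
    """Cutoff maximizing J = sensitivity + specificity - 1 (ties: lower cutoff)."""
    j = roc.sensitivity + roc.specificity - 1.0
    best_j = j.max()
    idx = np.flatnonzero(np.isclose(j, best_j, rtol=0, atol=1e-12))
    pick = idx[np.argmin(roc.cutoffs[idx])]
    return ThresholdResult(
        cutoff=float(roc.cutoffs[pick]),
        sensitivity=float(roc.sensitivity[pick]),
        specificity=float(roc.specificity[pick]),
        youden_j=float(j[pick]),
    )


@dataclass(frozen=True)
class GroupComparison:
    """KM curves and log-rank test for a feature dichotomized at a cutoff."""

    km_high: KmCurve
    km_low: KmCurve
    statistic: float
    p_value: float
    n_high: int
    n_low: int


def compare_at_threshold(time, event, feature, cutoff: float) -> GroupComparison:
    """Dichotomize at the cutoff (>= is 'high'), KM per group, log-rank p."""
    t, e = _as_arrays(time, event)
    f = np.asarray(feature, dtype=float)
    high = f >= cutoff
    if high.all() or not high.any():
        raise ValidationError(f"cutoff {cutoff} does not split the cohort into two groups")
    stat, p = logrank_test(t[high], e[high], t[~high], e[~high])
    return GroupComparison(
        km_high=km_estimate(t[high], e[high]),
        km_low=km_estimate(t[~high], e[~high]),
        statistic=stat,
        p_value=p,
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
    )
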