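"""Survival machinery shared by all stages: Kaplan-Meier with Greenwood
variance, k-group log-rank, multivariable Cox (Efron ties, Wald 95% CIs),
and inverse-probability-of-censoring-weighted cumulative/dynamic AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import chi2
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

from .core_io import ClinicalTable

__all__ = ["SurvFit", "CoxFit", "km_logrank", "cox_fit", "td_auc", "logrank_z"]


@dataclass
class KmCurve:
    times: np.ndarray  # ordered distinct event times
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray  # product-limit estimate at each event time
    variance: np.ndarray  # Greenwood variance


@dataclass
class SurvFit:
    curves: dict[str, KmCurve]
    chi2: float
    p: float
    df: int


@dataclass
class CoxFit:
    table: pd.DataFrame  # coef, hr, hr_lo, hr_hi, se, p per covariate
    lr_statistic: float
    lr_p: float
    ties: str = "efron"
    separation_flagged: bool = False


def _km_curve(time: np.ndarray, event: np.ndarray) -> KmCurve:
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    ev_times = np.unique(t[e == 1])
    n = len(t)
    at_risk = np.array([(t >= u).sum() for u in ev_times], dtype=float)
    d = np.array([((t == u) & (e == 1)).sum() for u in ev_times], dtype=float)
    surv = np.cumprod(1.0 - d / at_risk)
    # Greenwood: Var(S) = S^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(at_risk > d, d / (at_risk * (at_risk - d)), 0.0)
    var = surv**2 * np.cumsum(inc)
    return KmCurve(times=ev_times, at_risk=at_risk, events=d, survival=surv, variance=var)


def km_logrank(clinical: ClinicalTable, groups: pd.Series | dict) -> SurvFit:
    """Product-limit curves per group and the k-group log-rank test."""
    g = pd.Series(groups).loc[clinical.sample_ids]
    time, event = clinical.time, clinical.event
    if event.sum() == 0:
        raise ValueError("no events observed; survival analysis undefined")
    curves = {}
    for level in pd.unique(g):
        mask = (g == level).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"group {level!r} has no samples")
        curves[str(level)] = _km_curve(time[mask], event[mask])
    res = multivariate_logrank_test(time, g.to_numpy(), event)
    return SurvFit(
        curves=curves,
        chi2=float(res.test_statistic),
        p=float(res.p_value),
        df=len(curves) - 1,
    )


def cox_fit(
    clinical: ClinicalTable,
    covariates: list[str] | pd.DataFrame,
    alpha: float = 0.05,
) -> CoxFit:
    """Efron-ties Cox proportional hazards fit with Wald 95% CIs.

    ``covariates`` is either a list of clinical-table column names or a
    numeric samples x covariates frame aligned to the clinical table. A
    rank-deficient design is an error; monotone-likelihood (separated)
    fits are flagged and their coefficients capped at +/-10.
    """
    if isinstance(covariates, pd.DataFrame):
        design = covariates.loc[clinical.sample_ids].astype(float)
    else:
        design = clinical.data[list(covariates)].astype(float)
    X = design.to_numpy()
    if np.linalg.matrix_rank(np.column_stack([X, np.ones(len(X))])) <= X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    n_events = int(clinical.event.sum())
    if n_events < X.shape[1]:
        warnings.warn(
            f"only {n_events} events for {X.shape[1]} covariates", stacklevel=2
        )
    df = design.copy()
    df["time"] = clinical.time
    df["event"] = clinical.event

    fitter = CoxPHFitter(alpha=alpha)
    flagged = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fitter.fit(df, duration_col="time", event_col="event")
        flagged = any("convergence" in str(w.message).lower() for w in caught)
    summary = fitter.summary
    coef = summary["coef"].clip(-10, 10)
    if (summary["coef"].abs() > 10).any():
        flagged = True
        warnings.warn("separation suspected; coefficients capped at |10|", stacklevel=2)
    z = chi2.ppf(1 - alpha, 1) ** 0.5
    table = pd.DataFrame(
        {
            "coef": coef,
            "hr": np.exp(coef),
            "hr_lo": np.exp(coef - z * summary["se(coef)"]),
            "hr_hi": np.exp(coef + z * summary["se(coef)"]),
            "se": summary["se(coef)"],
            "p": summary["p"],
        }
    )
    lr = fitter.log_likelihood_ratio_test()
    return CoxFit(
        table=table,
        lr_statistic=float(lr.test_statistic),
        lr_p=float(lr.p_value),
        separation_flagged=flagged,
    )


def logrank_z(time: np.ndarray, event: np.ndarray, in_group: np.ndarray) -> float:
    """Standardized two-group log-rank statistic (O - E) / sqrt(V).

    Positive when the ``in_group`` arm has more events than expected
    (worse survival). Used both for testing and for maximally selected
    cutpoint scanning.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    in_group = np.asarray(in_group, bool)
    ev_times = np.unique(time[event == 1])
    U = 0.0
    V = 0.0
    for u in ev_times:
        at_risk = time >= u
        n = at_risk.sum()
        n1 = (at_risk & in_group).sum()
        dying = (time == u) & (event == 1)
        d = dying.sum()
        d1 = (dying & in_group).sum()
        U += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V <= 0:
        return 0.0
    return float(U / np.sqrt(V))


def td_auc(
    scores: pd.Series | np.ndarray,
    clinical: ClinicalTable,
    horizon: float | list[float],
) -> dict[float, float]:
    """Cumulative/dynamic AUC(t) with IPC weights from the censoring KM.

    Cases at t are subjects with an event by t, controls those still at
    risk beyond t; both must be non-empty at every requested horizon.
    """
    if isinstance(scores, pd.Series):
        scores = scores.loc[clinical.sample_ids].to_numpy(dtype=float)
    scores = np.asarray(scores, dtype=float)
    time, event = clinical.time, clinical.event
    horizons = np.atleast_1d(np.asarray(horizon, dtype=float))
    for t in horizons:
        if not (time.min() <= t < time.max()):
            raise ValueError(f"horizon {t} outside observed follow-up")
        if ((time <= t) & (event == 1)).sum() == 0:
            raise ValueError(f"no cases by t={t}")
        if (time > t).sum() == 0:
            raise ValueError(f"no controls beyond t={t}")
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    auc, _ = cumulative_dynamic_auc(y, y, scores, horizons)
    return {float(t): float(a) for t, a in zip(horizons, auc)}
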