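"""Kaplan-Meier estimation, log-rank tests and multivariate Cox models.

Cluster comparisons default to 5-year overall survival: subjects still at
risk past 60 months are administratively censored at 60.  Cox models use
Efron tie handling (Breslow by flag) and report hazard ratios with Wald
confidence intervals; the cluster contrasts are indicators against the
best-prognosis reference cluster with binary stage as covariate.

Estimation is delegated to lifelines; this module owns the truncation
rule, the contrast coding and the result contracts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

logger = logging.getLogger("luadstrat")

FIVE_YEARS_MONTHS = 60.0


@dataclass
class SurvivalCurve:
    times: np.ndarray  # observed event times
    at_risk: np.ndarray
    survival: np.ndarray  # product-limit S(t) at each event time
    censor_times: np.ndarray


@dataclass
class CoxResult:
    table: pd.DataFrame  # index covariate; columns hr, ci_low, ci_high, p, coef, se
    ties: str
    n: int
    n_events: int


def truncate_followup(
    time: pd.Series, event: pd.Series, horizon: float = FIVE_YEARS_MONTHS
) -> tuple[pd.Series, pd.Series]:
    """Administrative censoring at ``horizon`` months."""
    t = time.astype(float).copy()
    e = event.astype(int).copy()
    late = t > horizon
    e[late] = 0
    t[late] = horizon
    return t, e


def km_fit(time, event, five_year: bool = False) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate (optionally truncated at 60 months)."""
    time = pd.Series(np.asarray(time, dtype=float))
    event = pd.Series(np.asarray(event, dtype=int))
    if len(time) == 0:
        raise ValueError("no subjects")
    if (time < 0).any():
        raise ValueError("times must be >= 0")
    if five_year:
        time, event = truncate_followup(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    event_times = np.sort(time[event == 1].unique())
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    at_risk = np.array([(time >= t).sum() for t in event_times])
    censor_times = np.sort(time[event == 0].to_numpy())
    return SurvivalCurve(
        times=event_times, at_risk=at_risk, survival=surv, censor_times=censor_times
    )


def logrank(time, event, groups, five_year: bool = True) -> tuple[float, float]:
    """Log-rank chi-square statistic and p across >=2 groups."""
    time = pd.Series(np.asarray(time, dtype=float))
    event = pd.Series(np.asarray(event, dtype=int))
    groups = pd.Series(np.asarray(groups))
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValueError("need >=2 groups")
    if (counts == 0).any():
        raise ValueError("empty group")
    if five_year:
        time, event = truncate_followup(time, event)
    res = multivariate_logrank_test(time, groups, event)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    time,
    event,
    covariates: pd.DataFrame,
    ties: str = "efron",
    five_year: bool = True,
) -> CoxResult:
    """Multivariate Cox proportional-hazards fit.

    ``covariates`` holds the already-coded design (cluster indicators,
    binary stage, ...).  Efron tie handling by default; Wald CIs and p.
    """
    df = covariates.copy().astype(float)
    time = pd.Series(np.asarray(time, dtype=float), index=df.index)
    event = pd.Series(np.asarray(event, dtype=int), index=df.index)
    if event.sum() < 1:
        raise ValueError("need at least one event")
    rank = np.linalg.matrix_rank(df.to_numpy())
    if rank < df.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    if five_year:
        time, event = truncate_followup(time, event)
    if ties == "efron":
        data = df.assign(_time=time, _event=event)
        cph = CoxPHFitter()
        try:
            cph.fit(data, duration_col="_time", event_col="_event")
        except Exception as exc:
            raise RuntimeError(f"Cox fit failed: {exc}") from exc
        summary = cph.summary
        table = pd.DataFrame(
            {
                "hr": summary["exp(coef)"],
                "ci_low": summary["exp(coef) lower 95%"],
                "ci_high": summary["exp(coef) upper 95%"],
                "p": summary["p"],
                "coef": summary["coef"],
                "se": summary["se(coef)"],
            }
        )
    elif ties == "breslow":
        from sksurv.linear_model import CoxPHSurvivalAnalysis

        y = np.array(
            [(bool(e), t) for e, t in zip(event, time)],
            dtype=[("event", bool), ("time", float)],
        )
        model = CoxPHSurvivalAnalysis(ties="breslow")
        model.fit(df, y)
        coef = model.coef_
        # Wald quantities from the observed information
        cov = np.linalg.inv(_breslow_information(df.to_numpy(), time.to_numpy(),
                                                 event.to_numpy(), coef))
        se = np.sqrt(np.diag(cov))
        from scipy import stats as _st

        z = coef / se
        table = pd.DataFrame(
            {
                "hr": np.exp(coef),
                "ci_low": np.exp(coef - 1.96 * se),
                "ci_high": np.exp(coef + 1.96 * se),
                "p": 2 * _st.norm.sf(np.abs(z)),
                "coef": coef,
                "se": se,
            },
            index=df.columns,
        )
    else:
        raise ValueError("ties must be 'efron' or 'breslow'")
    return CoxResult(
        table=table, ties=ties, n=len(df), n_events=int(event.sum())
    )


def _breslow_information(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                         beta: np.ndarray) -> np.ndarray:
    """Observed information of the Breslow partial likelihood at ``beta``."""
    order = np.argsort(-time, kind="stable")
    X, time, event = X[order], time[order], event[order]
    eta = X @ beta
    w = np.exp(eta)
    info = np.zeros((X.shape[1], X.shape[1]))
    s0 = 0.0
    s1 = np.zeros(X.shape[1])
    s2 = np.zeros((X.shape[1], X.shape[1]))
    i = 0
    n = len(time)
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        for idx in range(i, j):  # extend risk set by this time's subjects
            s0 += w[idx]
            s1 += w[idx] * X[idx]
            s2 += w[idx] * np.outer(X[idx], X[idx])
        for idx in range(i, j):
            if event[idx]:
                xbar = s1 / s0
                info += s2 / s0 - np.outer(xbar, xbar)
        i = j
    return info


def cluster_cox(
    time,
    event,
    clusters: pd.Series,
    stage_binary: pd.Series | None = None,
    reference=None,
    five_year: bool = True,
) -> CoxResult:
    """Cox model with cluster indicators vs the reference (default: last cluster)."""
    levels = sorted(clusters.unique())
    reference = levels[-1] if reference is None else reference
    X = pd.DataFrame(
        {
            f"cluster_{c}_vs_{reference}": (clusters == c).astype(float)
            for c in levels
            if c != reference
        },
        index=clusters.index,
    )
    if stage_binary is not None:
        X["stage_high"] = stage_binary.reindex(clusters.index).astype(float)
    return cox_fit(time, event, X, five_year=five_year)
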