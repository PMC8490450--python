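"""Five-year-censored survival comparison across tumor classes.

Kaplan-Meier product-limit curves, k-group log-rank tests, and Cox
proportional-hazards models (Efron tie handling) over class labels and
clinical covariates, with HCC as the conventional referent class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .io import ClinicalTable

logger = logging.getLogger(__name__)

FIVE_YEARS_DAYS = 1826  # 5 x 365.25, rounded


def censor_at(clinical: ClinicalTable, horizon_days: float = FIVE_YEARS_DAYS) -> ClinicalTable:
    """Administratively censor follow-up at a horizon (default five years).

    Times strictly beyond the horizon are set to the horizon with
    event = 0; a time exactly at the horizon keeps its event indicator.
    """
    d = clinical.data.copy()
    over = d["time_days"] > horizon_days
    d.loc[over, "time_days"] = horizon_days
    d.loc[over, "event"] = 0
    return ClinicalTable(data=d)


@dataclass
class SurvivalCurve:
    """A Kaplan-Meier curve: event times, risk sets, and estimates."""

    event_times: np.ndarray  # ascending distinct event times
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray  # estimate just after each event time
    median_time: float  # first time the estimate drops to <= 0.5; nan if never

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival estimates must be non-increasing")
        if np.any(np.diff(self.at_risk) > 0):
            raise ValueError("at-risk counts must be non-increasing")


def km_estimate(times, events) -> SurvivalCurve:
    """Product-limit survival estimate with the first-crossing median rule."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    event_times = np.unique(times[events == 1])
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    at_risk = np.array([(times >= t).sum() for t in event_times])
    n_events = np.array([((times == t) & (events == 1)).sum() for t in event_times])
    crossing = event_times[surv <= 0.5]
    median_time = float(crossing[0]) if crossing.size else float("nan")
    return SurvivalCurve(
        event_times=event_times,
        at_risk=at_risk,
        events=n_events,
        survival=surv,
        median_time=median_time,
    )


def logrank_test(times, events, groups) -> tuple[float, int, float]:
    """k-group log-rank test; returns (chi-square, df, p)."""
    groups = pd.Series(list(groups))
    k = groups.nunique()
    if k < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    res = multivariate_logrank_test(
        np.asarray(times, dtype=float), groups, np.asarray(events, dtype=int)
    )
    return float(res.test_statistic), k - 1, float(res.p_value)


def cox_fit(
    clinical: ClinicalTable,
    covariates,
    referent_levels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties) over the given covariates.

    Categorical covariates are expanded to indicators against the stated
    referent level (defaulting to the alphabetically first level; the
    conventional referent for the class label is HCC). Returns a DataFrame
    indexed by expanded covariate with hazard_ratio, se_log_hr, p_value and
    the 95% CI. Warns when the event count is below five per parameter;
    errors on a constant covariate.
    """
    referent_levels = referent_levels or {}
    d = clinical.data
    design = pd.DataFrame(index=d.index)
    for cov in covariates:
        if cov not in d.columns:
            raise ValueError(f"covariate {cov!r} absent from clinical table")
        col = d[cov]
        if col.nunique() < 2:
            raise ValueError(f"covariate {cov!r} is constant: non-identifiable")
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.astype(str).unique())
            ref = str(referent_levels.get(cov, levels[0]))
            if ref not in levels:
                raise ValueError(f"referent {ref!r} is not a level of {cov!r}")
            for lvl in levels:
                if lvl != ref:
                    design[f"{cov}[{lvl}]"] = (col.astype(str) == lvl).astype(float)
        else:
            design[cov] = col.astype(float)
    n_events = int(d["event"].sum())
    if n_events < 5 * design.shape[1]:
        logger.warning(
            "only %d events for %d parameters (< 5 per parameter)",
            n_events,
            design.shape[1],
        )
    frame = design.assign(time_days=d["time_days"], event=d["event"])
    cph = CoxPHFitter()
    cph.fit(frame, duration_col="time_days", event_col="event")  # Efron ties default
    summary = cph.summary
    return pd.DataFrame(
        {
            "hazard_ratio": np.exp(summary["coef"]),
            "se_log_hr": summary["se(coef)"],
            "p_value": summary["p"],
            "ci_lower": np.exp(summary["coef lower 95%"]),
            "ci_upper": np.exp(summary["coef upper 95%"]),
        },
        index=summary.index,
    )


__all__ = [
    "FIVE_YEARS_DAYS",
    "SurvivalCurve",
    "censor_at",
    "km_estimate",
    "logrank_test",
    "cox_fit",
]
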