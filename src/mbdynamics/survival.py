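"""Survival analysis: Kaplan-Meier curves, multivariable Cox regression and
proportional-hazards checks.

Model fitting delegates to lifelines (Efron tie handling, the natural
choice for month-resolution event times); this module fixes the contracts
used by the rest of the pipeline: a KM curve table with median survival, a
per-covariate table of hazard ratios with Wald confidence intervals, and a
Schoenfeld-residual trend test per covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import proportional_hazard_test

__all__ = ["KMResult", "km_estimate", "cox_fit", "schoenfeld_trend", "cox_score_test"]


@dataclass
class KMResult:
    curve: pd.DataFrame  # time, survival, ci_low, ci_high
    median: float  # NaN when never reached

    def survival_at(self, t: float) -> float:
        past = self.curve[self.curve["time"] <= t]
        return float(past["survival"].iloc[-1]) if len(past) else 1.0


def km_estimate(times, events) -> KMResult:
    """Product-limit survival estimate.

    ``median`` is the earliest time with S(t) <= 0.5, NaN if the curve
    never reaches 0.5.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_
    curve = pd.DataFrame(
        {
            "time": sf.index.to_numpy(),
            "survival": sf.iloc[:, 0].to_numpy(),
            "ci_low": ci.iloc[:, 0].to_numpy(),
            "ci_high": ci.iloc[:, 1].to_numpy(),
        }
    )
    med = kmf.median_survival_time_
    median = float(med) if np.isfinite(med) else float("nan")
    return KMResult(curve=curve, median=median)


def cox_fit(records: pd.DataFrame, covariates: list[str], duration_col: str = "time", event_col: str = "event") -> tuple[pd.DataFrame, CoxPHFitter]:
    """Multivariable Cox proportional-hazards fit (Efron ties).

    Returns a per-covariate table (coef, HR, 95% CI, p) and the fitted
    lifelines model for downstream diagnostics.
    """
    if records[event_col].sum() < 1:
        raise ValueError("Cox regression requires at least one event")
    for c in covariates:
        if records[c].nunique() < 2:
            raise ValueError(f"constant covariate {c!r}")
    cph = CoxPHFitter()
    df = records[[duration_col, event_col] + covariates].copy()
    try:
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    except Exception as exc:  # convergence / separation
        raise RuntimeError(f"Cox fit failed: {exc}") from exc
    summ = cph.summary
    out = pd.DataFrame(
        {
            "covariate": summ.index,
            "coef": summ["coef"].to_numpy(),
            "hr": summ["exp(coef)"].to_numpy(),
            "hr_ci_low": np.exp(summ["coef lower 95%"].to_numpy()),
            "hr_ci_high": np.exp(summ["coef upper 95%"].to_numpy()),
            "p": summ["p"].to_numpy(),
        }
    ).reset_index(drop=True)
    return out, cph


def schoenfeld_trend(cph: CoxPHFitter, records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Trend test of scaled Schoenfeld residuals against (KM-transformed)
    event time; per-covariate p-values with a violation flag at ``alpha``."""
    if records[cph.event_col].sum() < 1:
        raise ValueError("no events: Schoenfeld residuals undefined")
    res = proportional_hazard_test(cph, records, time_transform="km")
    p = res.summary["p"]
    return pd.DataFrame(
        {"covariate": p.index.get_level_values(0), "p": p.to_numpy(), "violation": (p < alpha).to_numpy()}
    ).reset_index(drop=True)


def cox_score_test(times, events, group) -> float:
    """Score test statistic at beta = 0 for a single binary covariate
    (Breslow form, no ties assumed): U(0)^2 / I(0).

    For a binary group indicator without tied event times this equals the
    log-rank chi-square statistic.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    group = np.asarray(group, dtype=float)
    order = np.argsort(times)
    times, events, group = times[order], events[order], group[order]
    u = 0.0
    info = 0.0
    for i in np.nonzero(events)[0]:
        at_risk = times >= times[i]
        gbar = group[at_risk].mean()
        u += group[i] - gbar
        info += group[at_risk].var()  # E[g^2] - E[g]^2 over the risk set
    if info <= 0:
        raise ValueError("no information: constant group within risk sets")
    return float(u**2 / info)
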