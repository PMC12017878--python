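"""Kaplan–Meier estimation, proportional-hazards fitting and model checks.

The survival layer quantifies how diagnostic delay shifts mortality: the
product-limit estimator of survival per delay category, a Cox
proportional-hazards fit of the per-category hazard ratios (partial
likelihood, Breslow tie handling), restricted-mean life-years lost between
a reference and an exposed survival curve, and the calibration /
discrimination / prediction-error statistics used to validate the cohort
model (Hosmer–Lemeshow, concordance, MAPE, RMSE).

Kaplan–Meier curves come from lifelines and the partial-likelihood fit
from statsmodels; this module wraps both behind the pipeline's schema
(cohort CSV in, fit summaries and step curves out).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from . import params

__all__ = [
    "KMCurve",
    "HazardFit",
    "ValidationStats",
    "km_estimate",
    "ph_fit",
    "category_dummies",
    "life_years_lost",
    "rmst",
    "validation_stats",
]


@dataclass
class KMCurve:
    """Right-continuous product-limit survival step function."""

    times: np.ndarray          # distinct observed times, ascending
    survival: np.ndarray       # S(t) just after each time
    at_risk: np.ndarray
    events: np.ndarray
    max_observed: float

    def at(self, t: float) -> float:
        """S(t) for t >= 0 (1 before the first event)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
            }
        )


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimate with right censoring."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no observations supplied")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times < 0):
        raise ValueError("times must be nonnegative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    # keep rows for actual observation times (drop the synthetic t=0 row)
    tbl = kmf.event_table
    tbl = tbl[tbl["removed"] > 0]
    t = tbl.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(t).to_numpy()
    return KMCurve(
        times=t,
        survival=surv,
        at_risk=tbl["at_risk"].to_numpy(),
        events=tbl["observed"].to_numpy(),
        max_observed=float(times.max()),
    )


@dataclass
class HazardFit:
    """Cox proportional-hazards fit summary."""

    summary: pd.DataFrame      # index covariate; coef, se, hr, ci_lower, ci_upper
    n: int
    n_events: int

    def hr(self, name: str) -> float:
        return float(self.summary.loc[name, "hr"])

    def ci(self, name: str) -> tuple[float, float]:
        row = self.summary.loc[name]
        return float(row["ci_lower"]), float(row["ci_upper"])


def category_dummies(
    cohort: pd.DataFrame,
    column: str = "delay_category",
    reference: str = "<2w",
    ordering: tuple[str, ...] = params.DELAY_LABELS,
) -> pd.DataFrame:
    """Indicator columns for each non-reference level of a category."""
    levels = [lab for lab in ordering if lab != reference]
    out = pd.DataFrame(index=cohort.index)
    for lab in levels:
        out[f"{column}[{lab}]"] = (cohort[column] == lab).astype(float)
    return out


def ph_fit(
    cohort: pd.DataFrame,
    covariates: "list[str] | pd.DataFrame",
    duration_col: str = "time_months",
    event_col: str = "event",
) -> HazardFit:
    """Cox partial-likelihood fit with Breslow tie handling.

    ``covariates`` is either a list of numeric column names in ``cohort``
    or a ready-made numeric design frame (e.g. from
    :func:`category_dummies`).  Returns hazard ratios with 95% Wald
    confidence intervals.
    """
    X = cohort[covariates] if isinstance(covariates, list) else covariates
    X = X.astype(float)
    status = cohort[event_col].to_numpy(dtype=int)
    if status.sum() == 0:
        raise ValueError("no events in cohort; partial likelihood undefined")
    model = PHReg(
        cohort[duration_col].to_numpy(dtype=float),
        X.to_numpy(),
        status=status,
        ties="breslow",
    )
    try:
        res = model.fit()
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise RuntimeError(f"partial-likelihood fit failed to converge: {exc}")
    coef = np.asarray(res.params)
    se = np.asarray(res.bse)
    z = stats.norm.ppf(0.975)
    summary = pd.DataFrame(
        {
            "coef": coef,
            "se": se,
            "hr": np.exp(coef),
            "ci_lower": np.exp(coef - z * se),
            "ci_upper": np.exp(coef + z * se),
        },
        index=list(X.columns),
    )
    return HazardFit(summary=summary, n=len(cohort), n_events=int(status.sum()))


def rmst(curve: KMCurve, horizon_months: float) -> float:
    """Restricted mean survival time (months): step integral of S(t)."""
    if horizon_months > curve.max_observed:
        raise ValueError(
            f"horizon {horizon_months} exceeds curve support {curve.max_observed}"
        )
    knots = np.concatenate([[0.0], curve.times[curve.times < horizon_months]])
    values = np.concatenate([[1.0], curve.survival[curve.times < horizon_months]])
    widths = np.diff(np.concatenate([knots, [horizon_months]]))
    return float((values * widths).sum())


def life_years_lost(
    curve_ref: KMCurve, curve_exposed: KMCurve, horizon_months: float
) -> float:
    """Restricted-mean difference between two survival curves, in years."""
    return (rmst(curve_ref, horizon_months) - rmst(curve_exposed, horizon_months)) / 12.0


@dataclass
class ValidationStats:
    """Calibration, discrimination and prediction-error summary."""

    hosmer_lemeshow_stat: float
    hosmer_lemeshow_p: float
    c_statistic: float
    mape: float                # percent
    rmse: float


def _hosmer_lemeshow(p: np.ndarray, y: np.ndarray, bins: int = 10):
    """HL goodness-of-fit over equal-count risk deciles, chi2(bins-2)."""
    order = np.argsort(p, kind="stable")
    groups = np.array_split(order, bins)
    stat = 0.0
    used = 0
    for g in groups:
        if len(g) == 0:
            continue
        expected = p[g].sum()
        observed = y[g].sum()
        pbar = expected / len(g)
        denom = len(g) * pbar * (1.0 - pbar)
        if denom <= 0:
            continue
        stat += (observed - expected) ** 2 / denom
        used += 1
    df = max(used - 2, 1)
    return stat, float(stats.chi2.sf(stat, df))


def _concordance(p: np.ndarray, y: np.ndarray) -> float:
    """Probability a random event case outranks a random non-event case."""
    pos = p[y == 1]
    neg = p[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("concordance needs both event and non-event cases")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    return float(
        (ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2)
        / (len(pos) * len(neg))
    )


def validation_stats(
    predicted_probs,
    observed_events,
    predicted_values,
    observed_values,
    bins: int = 10,
) -> ValidationStats:
    """Model-validation statistics.

    Hosmer–Lemeshow calibration and the concordance statistic compare
    predicted event probabilities against binary outcomes; MAPE
    (percentage, over nonzero observations) and RMSE compare predicted
    against observed continuous values.
    """
    p = np.asarray(predicted_probs, dtype=float)
    y = np.asarray(observed_events, dtype=int)
    pred = np.asarray(predicted_values, dtype=float)
    obs = np.asarray(observed_values, dtype=float)
    if p.shape != y.shape or pred.shape != obs.shape:
        raise ValueError("prediction/observation vectors must align")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    nonzero = obs != 0
    if not nonzero.any():
        raise ValueError("MAPE undefined: all observed values are zero")
    hl_stat, hl_p = _hosmer_lemeshow(p, y, bins=bins)
    return ValidationStats(
        hosmer_lemeshow_stat=float(hl_stat),
        hosmer_lemeshow_p=hl_p,
        c_statistic=_concordance(p, y),
        mape=float(np.mean(np.abs(pred[nonzero] - obs[nonzero]) / np.abs(obs[nonzero])) * 100.0),
        rmse=float(np.sqrt(np.mean((pred - obs) ** 2))),
    )
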