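"""Censoring weights, crude and Kaplan-Meier risks, synergy, and PAF.

Emigration before age 3 censors a child's outcome.  When emigration depends
on baseline covariates, the complete-case risk is selection-biased; inverse
probability of censoring weighting (IPCW) reweights each uncensored child by
1 / P(uncensored | covariates), reconstructing the pseudo-population that
would have been observed without emigration.  Weights are unstabilized
(w >= 1), so the weighted n exceeds the raw n.

All risks are reported as deaths per 100 children.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .estimates import Z_95, EffectEstimate, RiskEstimate
from .simulate import ENTRY_AGE_YEARS, EXIT_AGE_YEARS, indicator


class SeparationError(ValueError):
    """Perfect separation in the censoring model."""


Predicate = Callable[[pd.DataFrame], np.ndarray]


def _as_mask(predicate, table: pd.DataFrame) -> np.ndarray:
    if isinstance(predicate, str):
        mask = indicator(table, predicate) > 0.5
    elif callable(predicate):
        mask = np.asarray(predicate(table))
    else:
        mask = np.asarray(predicate)
    if mask.shape[0] != len(table):
        raise ValueError("subgroup predicate length does not match cohort")
    return mask.astype(bool)


@dataclass
class WeightedCohort:
    """Uncensored children plus their IPCW weights; the unit all estimators consume."""

    data: pd.DataFrame
    weights: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    cohort_tag: str | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.data):
            raise ValueError("weights length does not match cohort")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite IPCW weight")
        if np.any(self.weights < 1.0 - 1e-12):
            raise ValueError("unstabilized IPCW weights must be >= 1")

    @property
    def weighted_n(self) -> float:
        return float(self.weights.sum())

    @classmethod
    def unweighted(cls, data: pd.DataFrame, cohort_tag: str | None = None) -> "WeightedCohort":
        return cls(data=data.reset_index(drop=True), weights=np.ones(len(data)), cohort_tag=cohort_tag)


@dataclass
class CensoringModel:
    covariate_names: tuple[str, ...]
    result: object | None  # fitted statsmodels GLM result; None => trivial P(censored)=0

    def prob_censored(self, table: pd.DataFrame) -> np.ndarray:
        if self.result is None:
            return np.zeros(len(table))
        X = _design(table, self.covariate_names)
        return np.asarray(self.result.predict(X))


def _design(table: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    cols = {"const": np.ones(len(table))}
    for name in covariates:
        col = table[name] if "=" not in name else None
        if col is not None and col.dtype == object:
            # expand a categorical into reference-dropped indicators
            levels = sorted(col.astype(str).unique())
            for level in levels[1:]:
                cols[f"{name}={level}"] = (col.astype(str) == level).astype(float)
        else:
            cols[name] = indicator(table, name)
    return pd.DataFrame(cols, index=table.index)


def fit_censoring_model(cohort: pd.DataFrame, covariates: Sequence[str]) -> CensoringModel:
    """Logistic regression of P(censored | baseline covariates).

    With no censored children the trivial model P(censored)=0 is returned.
    Perfect separation by a covariate raises SeparationError naming it.
    """
    y = cohort["censored"].to_numpy(dtype=float)
    if y.sum() == 0:
        return CensoringModel(tuple(covariates), None)
    if y.mean() == 1.0:
        raise ValueError("cohort has no uncensored children")
    X = _design(cohort, covariates)
    for col in X.columns:
        if col == "const":
            continue
        v = X[col].to_numpy()
        if len(np.unique(v)) < 2:
            continue
        # a binary covariate perfectly predicting censoring status
        tab = pd.crosstab(v > 0, y > 0)
        if tab.shape == (2, 2) and (tab.to_numpy() == 0).any():
            if ((y[v > 0].min() == y[v > 0].max()) or (y[v <= 0].min() == y[v <= 0].max())):
                raise SeparationError(f"perfect separation on covariate {col!r}")
    result = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    if not np.all(np.isfinite(result.params)) or np.abs(result.params).max() > 30:
        worst = X.columns[int(np.abs(result.params).argmax())]
        raise SeparationError(f"perfect separation on covariate {worst!r}")
    return CensoringModel(tuple(covariates), result)


def compute_ipcw(
    model: CensoringModel,
    cohort: pd.DataFrame,
    truncate_at: float = 10.0,
    cohort_tag: str | None = None,
) -> WeightedCohort:
    """Weight uncensored children by 1/P(uncensored), truncated at `truncate_at`."""
    if truncate_at <= 0:
        raise ValueError("truncate_at must be positive")
    p_cens = model.prob_censored(cohort)
    uncensored = cohort["censored"].to_numpy() == 0
    p_stay = 1.0 - p_cens[uncensored]
    if np.any(p_stay <= 0):
        raise ValueError("P(uncensored)=0 for an uncensored child; weights undefined")
    w = 1.0 / p_stay
    n_truncated = int((w > truncate_at).sum())
    w = np.minimum(w, truncate_at)
    data = cohort.loc[uncensored].reset_index(drop=True)
    diagnostics = {
        "n_raw": int(len(cohort)),
        "n_uncensored": int(uncensored.sum()),
        "weighted_n": float(w.sum()),
        "max_weight": float(w.max()),
        "mean_weight": float(w.mean()),
        "n_truncated": n_truncated,
        "truncate_at": truncate_at,
    }
    return WeightedCohort(data=data, weights=w, diagnostics=diagnostics, cohort_tag=cohort_tag)


def km_risk(cohort: pd.DataFrame, horizon: float = EXIT_AGE_YEARS) -> RiskEstimate:
    """Kaplan-Meier cumulative mortality risk by `horizon` (per 100 children).

    Children enter at 6 weeks; deaths and emigrations carry their observed
    ages, survivors are administratively censored at 3 years.  The CI is the
    log(-log) (exponential Greenwood) interval; the SE is the Greenwood SE
    of the survival probability.
    """
    from lifelines import KaplanMeierFitter

    if not (ENTRY_AGE_YEARS < horizon <= EXIT_AGE_YEARS):
        raise ValueError("horizon must lie in (6 weeks, 3 years]")
    died = cohort["died"].to_numpy()
    censored = cohort["censored"].to_numpy()
    durations = np.where(
        censored == 1,
        cohort["age_at_censoring"].to_numpy(),
        np.where(died == 1, cohort["age_at_death"].to_numpy(), EXIT_AGE_YEARS),
    )
    events = ((censored == 0) & (died == 1)).astype(int)
    if np.nanmax(durations) < horizon:
        raise ValueError("no children remain at risk at the horizon")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    s = float(kmf.predict(horizon))
    ci = kmf.confidence_interval_
    idx = ci.index.to_numpy()
    pos = int(np.searchsorted(idx, horizon, side="right")) - 1
    s_lo, s_hi = float(ci.iloc[pos, 0]), float(ci.iloc[pos, 1])
    # Greenwood variance from the event table
    tab = kmf.event_table
    upto = tab.index <= horizon
    d = tab.loc[upto, "observed"].to_numpy(dtype=float)
    r = tab.loc[upto, "at_risk"].to_numpy(dtype=float)
    keep = (d > 0) & (r > d)
    var = s**2 * float(np.sum(d[keep] / (r[keep] * (r[keep] - d[keep]))))
    return RiskEstimate(
        risk=(1.0 - s) * 100.0,
        se=np.sqrt(var) * 100.0,
        ci_low=(1.0 - max(s_lo, s_hi)) * 100.0,
        ci_high=(1.0 - min(s_lo, s_hi)) * 100.0,
        n=float(len(cohort)),
    )


def _weighted_risk(y: np.ndarray, w: np.ndarray, n_raw: int) -> RiskEstimate:
    wsum = w.sum()
    p = float(np.sum(w * y) / wsum)
    se = float(np.sqrt(np.sum(w**2 * (y - p) ** 2)) / wsum)
    return RiskEstimate(
        risk=p * 100.0,
        se=se * 100.0,
        ci_low=(p - Z_95 * se) * 100.0,
        ci_high=(p + Z_95 * se) * 100.0,
        n=float(n_raw),
        weighted_n=float(wsum),
    )


def crude_risk(wc: WeightedCohort, subgroup) -> tuple[RiskEstimate, RiskEstimate]:
    """Weighted crude mortality risks inside vs outside a subgroup (per 100)."""
    mask = _as_mask(subgroup, wc.data)
    if mask.all() or not mask.any():
        raise ValueError("very few children: subgroup must be nonempty on both sides")
    y = wc.data["died"].to_numpy(dtype=float)
    inside = _weighted_risk(y[mask], wc.weights[mask], int(mask.sum()))
    outside = _weighted_risk(y[~mask], wc.weights[~mask], int((~mask).sum()))
    return inside, outside


def risk_difference(
    risk_in: RiskEstimate | float,
    risk_out: RiskEstimate | float,
    se_in: float = 0.0,
    se_out: float = 0.0,
    cohort_tag: str | None = None,
) -> EffectEstimate:
    """Difference of two per-100 risks with SEs combined in quadrature."""
    if isinstance(risk_in, RiskEstimate):
        se_in = risk_in.se
        risk_in = risk_in.risk
    if isinstance(risk_out, RiskEstimate):
        se_out = risk_out.se
        risk_out = risk_out.risk
    for r in (risk_in, risk_out):
        if not 0.0 <= r <= 100.0:
            raise ValueError(f"risk {r} outside [0, 100] per-100")
    return EffectEstimate.wald(
        estimate=risk_in - risk_out,
        se=float(np.sqrt(se_in**2 + se_out**2)),
        method="crude",
        cohort_tag=cohort_tag,
    )


def synergy_statistic(
    wc: WeightedCohort,
    components: Sequence[str],
    calendar: str = "birth_year",
) -> EffectEstimate:
    """Additive interaction of a conjunction subgroup beyond its components.

    Weighted linear-probability model of death on {subgroup indicator, each
    component main effect, linear calendar time}; the subgroup-indicator
    coefficient (x100) with a robust sandwich SE is the excess risk above
    the sum of the single-factor effects.  No other confounders enter.
    """
    if len(components) < 2:
        raise ValueError("synergy requires at least two component covariates")
    y = wc.data["died"].to_numpy(dtype=float)
    comps = [indicator(wc.data, c) for c in components]
    sub = np.prod(np.column_stack(comps), axis=1)
    for c, arr in zip(components, comps):
        if np.array_equal(sub, arr):
            raise ValueError(f"subgroup is collinear with component {c!r}")
    year = wc.data[calendar].to_numpy(dtype=float)
    X = pd.DataFrame({"const": 1.0, "subgroup": sub})
    for c, arr in zip(components, comps):
        X[c] = arr
    X["calendar"] = year - year.mean()
    res = sm.WLS(y, X, weights=wc.weights).fit(cov_type="HC1")
    return EffectEstimate.wald(
        estimate=float(res.params["subgroup"]) * 100.0,
        se=float(res.bse["subgroup"]) * 100.0,
        method="synergy",
        adjustment_set=tuple(components) + (calendar,),
        cohort_tag=wc.cohort_tag,
    )


def paf(prevalence_exposed: float, amrd: float, overall_risk: float) -> float:
    """Population attributable fraction, in percent of all deaths.

    PAF = 100 * prevalence * aMRD / overall risk, with aMRD and the overall
    risk both per 100 children.  The fraction of deaths that would be
    prevented were the exposure's excess risk removed.
    """
    if overall_risk <= 0:
        raise ValueError("overall risk must be positive")
    if not 0.0 <= prevalence_exposed <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    return 100.0 * prevalence_exposed * amrd / overall_risk


def pooled_overall_risk(risks: Sequence[float], sizes: Sequence[float]) -> float:
    """Cohort-size-weighted mean of per-cohort risks (per 100)."""
    risks = np.asarray(risks, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    return float(np.sum(risks * sizes) / np.sum(sizes))


def write_weights(wc: WeightedCohort, csv_path: str | Path, report_path: str | Path | None = None) -> None:
    pd.DataFrame({"child_id": wc.data["child_id"], "weight": wc.weights}).to_csv(
        csv_path, index=False
    )
    if report_path is not None:
        Path(report_path).write_text(json.dumps(wc.diagnostics, indent=2))
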