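"""Backdoor-adjusted risk differences, TMLE, similarity tests, pooling.

Covariates live in an ordered causal hierarchy (environmental -> household
-> individual/birth) plus calendar time.  The backdoor adjustment set for
an exposure is calendar time together with every covariate in the domains
upstream of the exposure's own; sex and birth season are treated as
unconfounded and get an empty set.

tmle_risk_difference is a from-scratch targeted maximum likelihood
estimator of the additive effect of a binary subgroup indicator A on death,
per 100 children: a weighted logistic outcome regression Q(A, W), a
weighted logistic propensity g(W) truncated to [0.01, 0.99], a logistic
fluctuation with clever covariates A/g and (1-A)/(1-g) solved by Newton
iteration so the efficient-influence-curve equation holds to < 1e-8, and an
IC-based sandwich SE.  IPCW weights enter every regression as frequency
weights and scale the IC accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from scipy.stats import norm

from .estimates import EffectEstimate
from .weights import WeightedCohort, _as_mask, _design

_UNCONFOUNDED_DEFAULT = ("boy", "sex", "birth_season")
_DOMAIN_ORDER = ("environmental", "household", "individual")


@dataclass(frozen=True)
class CovariateSchema:
    """Domain assignment of every covariate plus the calendar covariate."""

    domains: Mapping[str, str]  # covariate name -> domain
    calendar: str = "birth_year"
    unconfounded: tuple[str, ...] = _UNCONFOUNDED_DEFAULT

    def __post_init__(self) -> None:
        for name, dom in self.domains.items():
            if dom not in _DOMAIN_ORDER:
                raise ValueError(f"unknown domain {dom!r} for covariate {name!r}")

    def in_domain(self, domain: str) -> list[str]:
        return [n for n, d in self.domains.items() if d == domain]


def schema_from_config(config) -> CovariateSchema:
    """Build the schema straight from a simulation configuration."""
    domains = {spec.name: spec.domain for spec in config.covariates}
    domains["birth_season"] = "individual"
    return CovariateSchema(domains=domains)


def adjustment_set(exposure: str, schema: CovariateSchema) -> tuple[str, ...]:
    """Backdoor adjustment set for a single exposure covariate."""
    base = exposure.split("=", 1)[0]
    if base in schema.unconfounded:
        return ()
    if base not in schema.domains:
        raise KeyError(f"unknown covariate {exposure!r}")
    domain = schema.domains[base]
    out = [schema.calendar]
    for upstream in _DOMAIN_ORDER[: _DOMAIN_ORDER.index(domain)]:
        out.extend(n for n in schema.in_domain(upstream) if n != base)
    return tuple(out)


def _adjustment_design(wc: WeightedCohort, covariates: Sequence[str], calendar: str) -> pd.DataFrame:
    X = _design(wc.data, [c for c in covariates if c != calendar])
    if calendar in covariates:
        year = wc.data[calendar].to_numpy(dtype=float)
        X["calendar"] = year - year.mean()
    return X


def glm_risk_difference(
    wc: WeightedCohort,
    exposure,
    adjustment: Sequence[str] = (),
    calendar: str = "birth_year",
) -> EffectEstimate:
    """Adjusted risk difference from a weighted linear-probability model.

    Death is regressed on the exposure indicator plus the adjustment set;
    the exposure coefficient x100 with a heteroskedasticity-robust sandwich
    SE is the adjusted MRD.  With an empty adjustment set and unit weights
    this equals the crude risk difference exactly.
    """
    a = _as_mask(exposure, wc.data).astype(float) if not isinstance(exposure, str) else None
    if a is None:
        from .simulate import indicator

        a = indicator(wc.data, exposure)
    if a.min() == a.max():
        raise ValueError("exposure does not vary")
    y = wc.data["died"].to_numpy(dtype=float)
    X = _adjustment_design(wc, adjustment, calendar)
    X.insert(1, "exposure", a)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError("collinear adjustment design")
    res = sm.WLS(y, X, weights=wc.weights).fit(cov_type="HC1")
    return EffectEstimate.wald(
        estimate=float(res.params["exposure"]) * 100.0,
        se=float(res.bse["exposure"]) * 100.0,
        method="glm_adjusted",
        adjustment_set=tuple(adjustment),
        cohort_tag=wc.cohort_tag,
    )


@dataclass
class TmleFit:
    """Internals of one targeted maximum likelihood fit."""

    q_init: np.ndarray        # Q(A, W) initial predictions
    q1: np.ndarray            # targeted Q*(1, W)
    q0: np.ndarray            # targeted Q*(0, W)
    g: np.ndarray             # truncated propensity P(A=1 | W)
    epsilon: tuple[float, float]
    psi: float                # per-100 risk difference
    influence_curve: np.ndarray
    se: float                 # per-100
    ic_mean: float
    g_truncated_fraction: float
    diagnostics: dict = field(default_factory=dict)


def _weighted_logistic(y, X, w, offset=None):
    model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w, offset=offset)
    return model.fit(maxiter=200)


def _fluctuation_newton(y, w, offset, h1, h0, tol=1e-12, max_iter=100):
    """Maximize the weighted Bernoulli likelihood in (eps1, eps0).

    Model: logit p = offset + eps1*h1 + eps0*h0.  Newton on the score;
    convergence criterion is the weight-normalized score, which is exactly
    the influence-curve equation the fluctuation must solve.
    """
    eps = np.zeros(2)
    H = np.column_stack([h1, h0])
    wsum = w.sum()
    for _ in range(max_iter):
        p = expit(offset + H @ eps)
        score = H.T @ (w * (y - p))
        if np.abs(score).max() / wsum < tol:
            break
        info = (H * (w * p * (1 - p))[:, None]).T @ H
        info += 1e-12 * np.eye(2)
        eps = eps + np.linalg.solve(info, score)
    return eps


def tmle_risk_difference(
    wc: WeightedCohort,
    subgroup,
    adjustment: Sequence[str] = (),
    calendar: str = "birth_year",
    g_bounds: tuple[float, float] = (0.01, 0.99),
) -> tuple[EffectEstimate, TmleFit]:
    """TMLE of the per-100 risk difference for subgroup membership."""
    a = _as_mask(subgroup, wc.data).astype(float)
    if a.min() == a.max():
        raise ValueError("subgroup indicator is one-sided")
    y = wc.data["died"].to_numpy(dtype=float)
    w = wc.weights

    W = _adjustment_design(wc, adjustment, calendar)  # includes const
    Xq = W.copy()
    Xq.insert(1, "A", a)

    q_res = _weighted_logistic(y, Xq, w)
    q_init = np.clip(np.asarray(q_res.predict(Xq)), 1e-9, 1 - 1e-9)
    X1 = Xq.copy()
    X1["A"] = 1.0
    X0 = Xq.copy()
    X0["A"] = 0.0
    q1_init = np.clip(np.asarray(q_res.predict(X1)), 1e-9, 1 - 1e-9)
    q0_init = np.clip(np.asarray(q_res.predict(X0)), 1e-9, 1 - 1e-9)

    if W.shape[1] == 1:  # no covariates: intercept-only propensity
        g_raw = np.full(len(a), np.average(a, weights=w))
    else:
        g_res = _weighted_logistic(a, W, w)
        g_raw = np.asarray(g_res.predict(W))
    g = np.clip(g_raw, g_bounds[0], g_bounds[1])
    trunc_frac = float(np.mean((g_raw < g_bounds[0]) | (g_raw > g_bounds[1])))

    h1 = a / g
    h0 = (1.0 - a) / (1.0 - g)
    eps = _fluctuation_newton(y, w, logit(q_init), h1, h0)
    q_star = expit(logit(q_init) + eps[0] * h1 + eps[1] * h0)
    q1 = expit(logit(q1_init) + eps[0] / g)
    q0 = expit(logit(q0_init) + eps[1] / (1.0 - g))

    wsum = w.sum()
    psi = float(np.sum(w * (q1 - q0)) / wsum)
    h_a = a / g - (1.0 - a) / (1.0 - g)
    ic = h_a * (y - q_star) + (q1 - q0) - psi
    ic_mean = float(np.sum(w * ic) / wsum)
    se = float(np.sqrt(np.sum(w**2 * ic**2)) / wsum)

    fit = TmleFit(
        q_init=q_init,
        q1=q1,
        q0=q0,
        g=g,
        epsilon=(float(eps[0]), float(eps[1])),
        psi=psi * 100.0,
        influence_curve=ic,
        se=se * 100.0,
        ic_mean=ic_mean,
        g_truncated_fraction=trunc_frac,
        diagnostics={
            "warn_g_truncation": trunc_frac > 0.05,
            "n": int(len(a)),
            "weighted_n": float(wsum),
        },
    )
    est = EffectEstimate.wald(
        estimate=psi * 100.0,
        se=se * 100.0,
        method="tmle",
        adjustment_set=tuple(adjustment),
        cohort_tag=wc.cohort_tag,
    )
    return est, fit


def similarity_test(e1: EffectEstimate, e2: EffectEstimate) -> float:
    """Two-sided z-test that two independent cohort estimates are equal."""
    if e1.cohort_tag is not None and e1.cohort_tag == e2.cohort_tag:
        raise ValueError("estimates share a cohort; the test assumes independence")
    if e1.se <= 0 or e2.se <= 0:
        raise ValueError("both standard errors must be positive")
    z = (e1.estimate - e2.estimate) / np.sqrt(e1.se**2 + e2.se**2)
    return float(2.0 * (1.0 - norm.cdf(abs(z))))


def combined_estimate(
    wc_hypothesis: WeightedCohort,
    wc_validation: WeightedCohort,
    subgroup,
    adjustment: Sequence[str] = (),
    calendar: str = "birth_year",
) -> tuple[EffectEstimate, TmleFit]:
    """Pooled TMLE over the concatenated cohorts, calendar time in W."""
    ids1 = set(wc_hypothesis.data["child_id"])
    ids2 = set(wc_validation.data["child_id"])
    if ids1 & ids2:
        raise ValueError("cohorts overlap; combined estimate requires disjoint children")
    data = pd.concat([wc_hypothesis.data, wc_validation.data], ignore_index=True)
    weights = np.concatenate([wc_hypothesis.weights, wc_validation.weights])
    pooled = WeightedCohort(data=data, weights=weights, cohort_tag="combined")
    adj = tuple(adjustment)
    if calendar not in adj:
        adj = (calendar,) + adj
    if callable(subgroup) or isinstance(subgroup, str):
        mask = np.concatenate(
            [_as_mask(subgroup, wc_hypothesis.data), _as_mask(subgroup, wc_validation.data)]
        )
    else:
        mask = _as_mask(subgroup, data)
    return tmle_risk_difference(pooled, mask, adj, calendar=calendar)
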