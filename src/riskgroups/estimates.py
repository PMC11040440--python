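"""Shared estimate containers.

Every effect in this package is reported on the additive risk scale as
deaths per 100 children (a mortality risk difference, MRD), with symmetric
Wald confidence intervals unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class RiskEstimate:
    """A risk (deaths per 100 children) with its uncertainty."""

    risk: float
    se: float
    ci_low: float
    ci_high: float
    n: float = float("nan")          # unweighted children contributing
    weighted_n: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.risk <= self.ci_high):
            raise ValueError(
                f"confidence interval [{self.ci_low}, {self.ci_high}] does not "
                f"bracket the risk {self.risk}"
            )


@dataclass(frozen=True)
class EffectEstimate:
    """A risk difference per 100 children.

    ``method`` records how the estimate was obtained (``crude``,
    ``glm_adjusted``, ``tmle`` or ``synergy``); ``adjustment_set`` the
    covariates conditioned on; ``cohort_tag`` which cohort produced it
    (``hypothesis``, ``validation`` or ``combined``).
    """

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    method: str = "crude"
    adjustment_set: tuple[str, ...] = field(default_factory=tuple)
    cohort_tag: str | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError(
                f"confidence interval [{self.ci_low}, {self.ci_high}] does not "
                f"bracket the estimate {self.estimate}"
            )

    @classmethod
    def wald(
        cls,
        estimate: float,
        se: float,
        method: str = "crude",
        adjustment_set: tuple[str, ...] = (),
        cohort_tag: str | None = None,
    ) -> "EffectEstimate":
        half = Z_95 * se
        return cls(
            estimate=estimate,
            se=se,
            ci_low=estimate - half,
            ci_high=estimate + half,
            method=method,
            adjustment_set=tuple(adjustment_set),
            cohort_tag=cohort_tag,
        )

    @classmethod
    def from_ci(
        cls,
        estimate: float,
        ci_low: float,
        ci_high: float,
        method: str = "crude",
        cohort_tag: str | None = None,
    ) -> "EffectEstimate":
        """Reconstruct a Wald estimate from a printed 95% CI (SE = width / 3.92)."""
        se = (ci_high - ci_low) / (2.0 * Z_95)
        return cls(
            estimate=estimate,
            se=se,
            ci_low=ci_low,
            ci_high=ci_high,
            method=method,
            cohort_tag=cohort_tag,
        )
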