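import numpy as np
import pandas as pd
import pytest

from riskgroups import simulate
from riskgroups.weights import WeightedCohort

NO_CENSORING = {"intercept": float("-inf")}


def plain_config(**overrides) -> simulate.SimulationConfig:
    """A stripped configuration: no planted structure unless overridden."""
    base = dict(
        n_children=50_000,
        seed=0,
        baseline_risk_by_year=(5.0, 0.0),
        domain_effect_sizes={},
        hotspot=None,
        synergy_pair=None,
        censoring_model=NO_CENSORING,
    )
    base.update(overrides)
    return simulate.SimulationConfig(**base)


@pytest.fixture(scope="session")
def null_cohort() -> pd.DataFrame:
    """50k children, flat 5 per-100 risk, no planted structure, no censoring."""
    return simulate.generate_cohort(plain_config(), keep_latent=True)


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """The full default study conditions (planted hotspot, synergy, censoring)."""
    return simulate.generate_cohort(simulate.SimulationConfig(seed=11), keep_latent=True)


def unweighted(cohort: pd.DataFrame, tag: str | None = None) -> WeightedCohort:
    return WeightedCohort.unweighted(cohort, cohort_tag=tag)


def toy_outcome_frame(outcome: np.ndarray, **columns) -> pd.DataFrame:
    """Minimal cohort-shaped frame for estimator tests."""
    n = len(outcome)
    frame = pd.DataFrame(
        {"child_id": [f"t{i}" for i in range(n)], "died": np.asarray(outcome, float)}
    )
    frame["censored"] = 0
    frame["birth_year"] = columns.pop("birth_year", np.full(n, 2005))
    for name, values in columns.items():
        frame[name] = values
    return frame
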