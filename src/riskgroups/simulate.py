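"""Synthetic HDSS-like child cohorts with planted high-risk structure.

The generator emulates an urban Health and Demographic Surveillance System
(HDSS) cohort of children followed from 6 weeks to 3 years of age: a
three-domain covariate hierarchy (environmental -> household -> individual/
birth), a linear decline of mortality with birth year, one spatial mortality
hotspot, one elevated single risk factor, one two-factor synergistic
subgroup, and non-random emigration (informative censoring).  Risks are
additive on the per-100 scale, so every planted effect is exactly the risk
difference the downstream estimators target.

A risk pattern whose additive risk would leave [0, 1] is a configuration
error, never silently clamped: clamping would corrupt the ground truth the
recovery tests rely on.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ENTRY_AGE_YEARS = 6 * 7 / 365.25  # follow-up starts at 6 weeks of age
EXIT_AGE_YEARS = 3.0


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class CovariateSpec:
    """One baseline covariate: binary (prevalence) or categorical (levels)."""

    name: str
    domain: str  # environmental | household | individual
    prevalence: float | None = None
    levels: tuple[str, ...] | None = None
    probs: tuple[float, ...] | None = None

    @property
    def is_binary(self) -> bool:
        return self.prevalence is not None

    def __post_init__(self) -> None:
        if self.domain not in ("environmental", "household", "individual"):
            raise ConfigurationError(f"unknown domain {self.domain!r} for {self.name!r}")
        if self.is_binary == (self.levels is not None):
            raise ConfigurationError(
                f"covariate {self.name!r} must be either binary or categorical"
            )
        if self.levels is not None:
            if self.probs is None or len(self.probs) != len(self.levels):
                raise ConfigurationError(f"covariate {self.name!r}: levels/probs mismatch")
            if abs(sum(self.probs) - 1.0) > 1e-9:
                raise ConfigurationError(f"covariate {self.name!r}: probs must sum to 1")


@dataclass(frozen=True)
class Hotspot:
    """Circular excess-risk area; density_multiplier > 1 concentrates homes inside."""

    center: tuple[float, float]
    radius: float
    excess: float  # per-100 additive risk inside the circle
    density_multiplier: float = 2.0


@dataclass(frozen=True)
class SynergyPair:
    """Two covariate indicators whose joint presence adds `excess` per-100."""

    a: str  # "column" for binary, "column=level" for categorical
    b: str
    excess: float


def _default_covariates() -> tuple[CovariateSpec, ...]:
    return (
        CovariateSpec("near_major_road", "environmental", prevalence=0.06),
        CovariateSpec("vegetation_top10", "environmental", prevalence=0.07),
        CovariateSpec("high_pop_density", "environmental", prevalence=0.09),
        CovariateSpec("maternal_schooling_lt7", "household", prevalence=0.61),
        CovariateSpec("crowding", "household", prevalence=0.83),
        CovariateSpec("polygamous", "household", prevalence=0.18),
        CovariateSpec("no_television", "household", prevalence=0.67),
        CovariateSpec(
            "ethnicity",
            "household",
            levels=("balanta", "fula_mandinga", "manjaco_mancanha", "pepel", "other"),
            probs=(0.08, 0.28, 0.19, 0.16, 0.29),
        ),
        CovariateSpec("twin", "individual", prevalence=0.03),
        CovariateSpec("boy", "individual", prevalence=0.51),
        CovariateSpec("no_prenatal_consultations", "individual", prevalence=0.04),
    )


# Per-100 additive increments applied when the indicator is 1.  The mean
# covariate load under the default prevalences is ~2.1 per-100, so with the
# baseline trend below the cohort-mean risks land near 5.2% (2003-2011) and
# 2.9% (2012-2016).
_DEFAULT_EFFECTS: dict[str, float] = {
    "no_prenatal_consultations": 3.9,
    "twin": 4.3,
    "maternal_schooling_lt7": 1.0,
    "crowding": 1.0,
    "polygamous": 0.5,
    "birth_season=dry": 0.3,
}


@dataclass(frozen=True)
class SimulationConfig:
    n_children: int = 21005
    birth_year_range: tuple[int, int] = (2003, 2016)
    seed: int = 0
    # (per-100 risk of the all-reference pattern at the first birth year,
    #  per-100 change per birth year)
    baseline_risk_by_year: tuple[float, float] = (4.5, -0.33)
    covariates: tuple[CovariateSpec, ...] = field(default_factory=_default_covariates)
    domain_effect_sizes: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_EFFECTS)
    )
    hotspot: Hotspot | None = Hotspot(center=(1000.0, 1200.0), radius=200.0, excess=4.0)
    synergy_pair: SynergyPair | None = SynergyPair("twin", "birth_season=rainy", 6.8)
    # logistic model of P(emigrated before age 3 | baseline covariates);
    # keys: "intercept" plus indicator specs.  Intercept -1.3 gives ~24%
    # censoring so the IPCW-weighted n inflates by roughly one third.
    censoring_model: Mapping[str, float] = field(
        default_factory=lambda: {"intercept": -1.3, "maternal_schooling_lt7": 0.3}
    )
    area_extent: tuple[float, float, float, float] = (0.0, 0.0, 3000.0, 3000.0)
    # optional logistic links child-covariate <- earlier-domain covariates,
    # e.g. {"crowding": {"intercept": 1.2, "high_pop_density": 0.5}}
    dependence: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def fingerprint(self) -> str:
        payload = json.dumps(_config_dict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["domain_effect_sizes"] = dict(config.domain_effect_sizes)
    d["censoring_model"] = dict(config.censoring_model)
    d["dependence"] = {k: dict(v) for k, v in config.dependence.items()}
    return d


def indicator(table: pd.DataFrame, spec: str) -> np.ndarray:
    """Evaluate an indicator spec: ``"col"`` (0/1 column) or ``"col=level"``."""
    if "=" in spec:
        col, level = spec.split("=", 1)
        if col not in table.columns:
            raise KeyError(f"unknown covariate {col!r}")
        return (table[col].astype(str) == level).to_numpy(dtype=float)
    if spec not in table.columns:
        raise KeyError(f"unknown covariate {spec!r}")
    return table[spec].to_numpy(dtype=float)


def _effect_bounds(config: SimulationConfig) -> tuple[float, list[str], float, list[str]]:
    """Worst-case additive load over covariate patterns (per-100)."""
    hi, hi_pattern, lo, lo_pattern = 0.0, [], 0.0, []
    for spec_name, eff in config.domain_effect_sizes.items():
        if eff > 0:
            hi += eff
            hi_pattern.append(spec_name)
        elif eff < 0:
            lo += eff
            lo_pattern.append(spec_name)
    if config.hotspot is not None:
        if config.hotspot.excess > 0:
            hi += config.hotspot.excess
            hi_pattern.append("hotspot")
        else:
            lo += config.hotspot.excess
            lo_pattern.append("hotspot")
    if config.synergy_pair is not None:
        if config.synergy_pair.excess > 0:
            hi += config.synergy_pair.excess
            hi_pattern.append(f"{config.synergy_pair.a} & {config.synergy_pair.b}")
        else:
            lo += config.synergy_pair.excess
            lo_pattern.append(f"{config.synergy_pair.a} & {config.synergy_pair.b}")
    return hi, hi_pattern, lo, lo_pattern


def _validate_risk_bounds(config: SimulationConfig) -> None:
    a, b = config.baseline_risk_by_year
    y0, y1 = config.birth_year_range
    base_lo = min(a, a + b * (y1 - y0))
    base_hi = max(a, a + b * (y1 - y0))
    hi, hi_pattern, lo, lo_pattern = _effect_bounds(config)
    if base_hi + hi > 100.0:
        raise ConfigurationError(
            f"risk exceeds 100 per-100 for pattern {{{', '.join(hi_pattern) or 'baseline'}}}"
            f" (baseline {base_hi:.2f} + effects {hi:.2f})"
        )
    if base_lo + lo < 0.0:
        raise ConfigurationError(
            f"risk below 0 per-100 for pattern {{{', '.join(lo_pattern) or 'baseline'}}}"
            f" (baseline {base_lo:.2f} + effects {lo:.2f})"
        )


def _sample_coordinates(config: SimulationConfig, n: int, rng: np.random.Generator):
    x0, y0, x1, y1 = config.area_extent
    hs = config.hotspot
    if hs is None:
        return rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)
    area_total = (x1 - x0) * (y1 - y0)
    area_hs = np.pi * hs.radius**2
    if area_hs >= area_total:
        raise ConfigurationError("hotspot larger than the study area")
    cx, cy = hs.center
    if not (x0 + hs.radius <= cx <= x1 - hs.radius and y0 + hs.radius <= cy <= y1 - hs.radius):
        raise ConfigurationError("hotspot circle must lie inside the area extent")
    m = hs.density_multiplier
    p_in = m * area_hs / (m * area_hs + (area_total - area_hs))
    inside = rng.random(n) < p_in
    x = np.empty(n)
    y = np.empty(n)
    k = int(inside.sum())
    r = hs.radius * np.sqrt(rng.random(k))
    theta = rng.uniform(0.0, 2.0 * np.pi, k)
    x[inside] = cx + r * np.cos(theta)
    y[inside] = cy + r * np.sin(theta)
    idx = np.flatnonzero(~inside)
    xo = rng.uniform(x0, x1, idx.size)
    yo = rng.uniform(y0, y1, idx.size)
    bad = (xo - cx) ** 2 + (yo - cy) ** 2 < hs.radius**2
    while bad.any():
        nb = int(bad.sum())
        xo[bad] = rng.uniform(x0, x1, nb)
        yo[bad] = rng.uniform(y0, y1, nb)
        bad = (xo - cx) ** 2 + (yo - cy) ** 2 < hs.radius**2
    x[idx] = xo
    y[idx] = yo
    return x, y


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def hotspot_membership(config: SimulationConfig, table: pd.DataFrame) -> np.ndarray:
    if config.hotspot is None:
        return np.zeros(len(table), dtype=bool)
    cx, cy = config.hotspot.center
    d2 = (table["x"].to_numpy() - cx) ** 2 + (table["y"].to_numpy() - cy) ** 2
    return d2 <= config.hotspot.radius**2


def synergy_membership(config: SimulationConfig, table: pd.DataFrame) -> np.ndarray:
    if config.synergy_pair is None:
        return np.zeros(len(table), dtype=bool)
    sp = config.synergy_pair
    return (indicator(table, sp.a) * indicator(table, sp.b)) > 0.5


def per_child_risk(config: SimulationConfig, table: pd.DataFrame) -> np.ndarray:
    """The configured additive per-100 risk for each child (the ground truth)."""
    a, b = config.baseline_risk_by_year
    y0 = config.birth_year_range[0]
    risk = a + b * (table["birth_year"].to_numpy() - y0)
    for spec_name, eff in config.domain_effect_sizes.items():
        risk = risk + eff * indicator(table, spec_name)
    if config.hotspot is not None:
        risk = risk + config.hotspot.excess * hotspot_membership(config, table)
    if config.synergy_pair is not None:
        risk = risk + config.synergy_pair.excess * synergy_membership(config, table)
    return risk


def generate_cohort(config: SimulationConfig, keep_latent: bool = False) -> pd.DataFrame:
    """Simulate one cohort table (one row per child).

    Columns: child_id, birth_year, birth_season, x, y, the configured
    covariates, censored, age_at_censoring, died, age_at_death.  ``died`` is
    NaN for censored (emigrated) children — their outcome is unobserved.
    With ``keep_latent=True`` the pre-censoring outcome is retained in
    ``died_latent`` for simulation studies.

    The same seed yields a byte-identical table, and the death draws do not
    depend on the censoring configuration (censoring uses later RNG draws).
    """
    if config.n_children < 1:
        raise ConfigurationError("n_children must be >= 1")
    y0, y1 = config.birth_year_range
    if y1 < y0:
        raise ConfigurationError("birth_year_range must be increasing")
    _validate_risk_bounds(config)

    rng = np.random.default_rng(config.seed)
    n = config.n_children
    table = pd.DataFrame(
        {
            "child_id": [f"c{i:07d}" for i in range(n)],
            "birth_year": rng.integers(y0, y1 + 1, n),
        }
    )
    # dry/rainy split independent of year (observed split is ~51/49)
    table["birth_season"] = np.where(rng.random(n) < 0.5, "dry", "rainy")
    x, y = _sample_coordinates(config, n, rng)
    table["x"] = x
    table["y"] = y

    for spec in config.covariates:
        if spec.name in config.dependence:
            link = config.dependence[spec.name]
            if not spec.is_binary:
                raise ConfigurationError(
                    f"dependence links are only supported for binary covariates "
                    f"({spec.name!r} is categorical)"
                )
            z = np.full(n, float(link.get("intercept", 0.0)))
            for parent, beta in link.items():
                if parent == "intercept":
                    continue
                z = z + beta * indicator(table, parent)
            p = _logistic(z)
            table[spec.name] = (rng.random(n) < p).astype(int)
        elif spec.is_binary:
            table[spec.name] = (rng.random(n) < spec.prevalence).astype(int)
        else:
            table[spec.name] = rng.choice(spec.levels, size=n, p=spec.probs)

    risk = per_child_risk(config, table)
    if (risk < 0).any() or (risk > 100).any():
        i = int(np.argmax((risk < 0) | (risk > 100)))
        raise ConfigurationError(
            f"child pattern {table.iloc[i].to_dict()} has risk {risk[i]:.2f} per-100"
        )
    died = (rng.random(n) < risk / 100.0).astype(int)
    age_death = rng.uniform(ENTRY_AGE_YEARS, EXIT_AGE_YEARS, n)

    cm = dict(config.censoring_model)
    z = np.full(n, float(cm.pop("intercept", -np.inf)))
    for spec_name, beta in cm.items():
        ind = indicator(table, spec_name)
        with np.errstate(invalid="ignore"):
            term = beta * ind
        term = np.where(ind == 0.0, 0.0, term)  # -inf coefficient only hits exposed
        z = z + term
    p_cens = np.where(np.isneginf(z), 0.0, _logistic(z))
    censored = (rng.random(n) < p_cens).astype(int)
    age_cens = rng.uniform(ENTRY_AGE_YEARS, EXIT_AGE_YEARS, n)

    table["censored"] = censored
    table["age_at_censoring"] = np.where(censored == 1, age_cens, np.nan)
    table["died"] = np.where(censored == 1, np.nan, died.astype(float))
    table["age_at_death"] = np.where((censored == 0) & (died == 1), age_death, np.nan)
    if keep_latent:
        table["died_latent"] = died
        table["true_risk_per100"] = risk
    table.attrs["config_fingerprint"] = config.fingerprint()
    table.attrs["seed"] = config.seed
    return table


def true_subgroup_labels(config: SimulationConfig, cohort: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth membership indicators for the planted subgroups.

    The cohort must carry the fingerprint of `config` (set by
    generate_cohort / read_cohort); a mismatch raises, guarding against
    labelling a cohort with the wrong configuration.
    """
    fp = cohort.attrs.get("config_fingerprint")
    if fp != config.fingerprint():
        raise ValueError("cohort fingerprint does not match this configuration")
    return pd.DataFrame(
        {
            "child_id": cohort["child_id"].to_numpy(),
            "hotspot": hotspot_membership(config, cohort),
            "synergy": synergy_membership(config, cohort),
        }
    )


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write the cohort CSV plus a JSON sidecar (fingerprint, seed, schema)."""
    path = Path(path)
    cohort.to_csv(path, index=False)
    sidecar = {
        "config_fingerprint": cohort.attrs.get("config_fingerprint"),
        "seed": cohort.attrs.get("seed"),
        "n_children": int(len(cohort)),
        "columns": list(cohort.columns),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_cohort(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    table = pd.read_csv(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        table.attrs["config_fingerprint"] = sidecar.get("config_fingerprint")
        table.attrs["seed"] = sidecar.get("seed")
    return table


def covariate_columns(config: SimulationConfig, domains: Sequence[str] | None = None) -> list[str]:
    """Names of the configured covariate columns, optionally by domain."""
    out = []
    for spec in config.covariates:
        if domains is None or spec.domain in domains:
            out.append(spec.name)
    return out
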