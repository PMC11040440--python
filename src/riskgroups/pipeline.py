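"""Inductive-deductive pipeline: discover on the early cohort, validate later.

The cohort is split by birth year (default: births through 2011 form the
hypothesis-generating cohort, later births the temporal validation cohort).
Discovery — spatial scan maxima, single risk factors with CI excluding 0,
and Causes of Outcome Learning cluster rules — runs only on the hypothesis
cohort, and the resulting candidate list is frozen with a content hash.
Validation then recomputes, for each frozen rule, both cohorts' crude
risks, the synergy statistic (for conjunctions), TMLE-adjusted risk
differences with domain-graded adjustment sets, a cross-cohort similarity
test, a pooled combined estimate, and the population attributable fraction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import cool, effects, spatial, weights
from .estimates import EffectEstimate
from .rules import Rule, SpatialRule, rules_digest
from .simulate import SimulationConfig
from .weights import WeightedCohort


@dataclass(frozen=True)
class StudyConfig:
    split_year: int = 2011            # last birth year of the hypothesis cohort
    min_count: int = 100              # spatial masking threshold (children per window)
    window: float = 250.0
    step: float = 10.0
    spatial_candidate_radius: float = 250.0
    spatial_excess_threshold: float = 2.0   # per-100 above the global adjusted risk
    cool_min_prevalence: float = 0.005
    cool_max_groups: int = 8
    cool_rule_threshold: float = 0.5
    few_children_threshold: int = 20  # "very few children" suppression per cell
    truncate_weights_at: float = 10.0
    seed: int = 0
    cool_hyperparams: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        study = {k: v for k, v in raw.get("study", raw).items() if k in known}
        return cls(**study)


def temporal_split(cohort: pd.DataFrame, split_year: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition by birth year: hypothesis <= split_year < validation."""
    years = cohort["birth_year"]
    hyp = cohort.loc[years <= split_year].reset_index(drop=True)
    val = cohort.loc[years > split_year].reset_index(drop=True)
    if len(hyp) == 0 or len(val) == 0:
        raise ValueError(f"temporal split at {split_year} leaves one side empty")
    for part in (hyp, val):
        part.attrs = dict(cohort.attrs)
    return hyp, val


def build_weighted(
    cohort: pd.DataFrame,
    covariates: Sequence[str],
    truncate_at: float = 10.0,
    cohort_tag: str | None = None,
) -> WeightedCohort:
    """Fit the censoring model and return the IPCW-weighted cohort."""
    model = weights.fit_censoring_model(cohort, covariates)
    return weights.compute_ipcw(model, cohort, truncate_at=truncate_at, cohort_tag=cohort_tag)


def _local_maxima(surface: spatial.RiskSurface, threshold: float, max_areas: int = 4):
    """Greedy non-overlapping peaks above threshold (non-inferential helper)."""
    risk = surface.risk.copy()
    geom = surface.geometry
    out = []
    min_sep = geom.window  # peaks at least one window apart
    while len(out) < max_areas and not np.all(np.isnan(risk)):
        j, i = np.unravel_index(np.nanargmax(risk), risk.shape)
        if risk[j, i] < threshold:
            break
        cx, cy = geom.node_center(int(i), int(j))
        out.append((cx, cy, float(risk[j, i])))
        ii, jj = np.meshgrid(np.arange(geom.nx), np.arange(geom.ny))
        xs = geom.x0 + geom.step * ii + geom.window / 2.0
        ys = geom.y0 + geom.step * jj + geom.window / 2.0
        risk[(xs - cx) ** 2 + (ys - cy) ** 2 < min_sep**2] = np.nan
    return out


def run_discovery(
    wc_hyp: WeightedCohort,
    study: StudyConfig,
    schema: effects.CovariateSchema,
    bbox: tuple[float, float, float, float],
    single_factors: Sequence[str] = (),
    cool_binary: Sequence[str] = (),
    cool_categorical: Sequence[str] = (),
    enable_spatial: bool = True,
    enable_single: bool = True,
    enable_cool: bool = True,
) -> list[Rule | SpatialRule]:
    """Propose candidate subgroups from the hypothesis cohort only."""
    candidates: list[Rule | SpatialRule] = []

    if enable_spatial:
        surface = spatial.scan(
            wc_hyp, bbox, min_count=study.min_count, step=study.step, window=study.window
        )
        threshold = surface.global_risk + study.spatial_excess_threshold
        for cx, cy, peak in _local_maxima(surface, threshold):
            candidates.append(
                SpatialRule(
                    center=(cx, cy),
                    radius=study.spatial_candidate_radius,
                    detail={"peak_risk_per100": peak},
                )
            )

    if enable_single:
        for factor in single_factors:
            adj = effects.adjustment_set(factor, schema)
            try:
                est = effects.glm_risk_difference(wc_hyp, factor, adj)
            except ValueError:
                continue
            if est.ci_low > 0:
                candidates.append(
                    Rule(
                        conditions=((factor.split("=")[0], factor.split("=")[1] if "=" in factor else 1),),
                        provenance="single_factor",
                        detail={"amrd": est.estimate, "ci": [est.ci_low, est.ci_high]},
                    )
                )

    if enable_cool:
        hp_kwargs = dict(study.cool_hyperparams)
        hp_kwargs.setdefault("seed", study.seed)
        hp = cool.CoolHyperparams(**hp_kwargs)
        design = cool.encode_features(
            wc_hyp.data,
            binary=cool_binary,
            categorical=cool_categorical,
            weights=wc_hyp.weights,
        )
        model = cool.train_cool(design, hp)
        profile = cool.risk_contributions(model, design)
        result = cool.extract_subgroups(
            profile,
            design,
            max_groups=study.cool_max_groups,
            min_prevalence=study.cool_min_prevalence,
        )
        overall = float(np.sum(design.weights * design.y) / design.weights.sum()) * 100.0
        for group in result.groups:
            if group.flagged_small or group.weighted_mean_risk <= overall:
                continue
            if group.mean_contributions.max() <= 1e-6:
                continue
            try:
                rule = cool.subgroup_to_rule(
                    result, group.label, design, threshold=study.cool_rule_threshold
                )
            except ValueError:
                continue
            rule = Rule(
                conditions=rule.conditions,
                provenance="cool",
                detail={
                    "group": group.label,
                    "prevalence": group.prevalence,
                    "mean_risk_per100": group.weighted_mean_risk,
                },
            )
            if rule.conditions and rule not in candidates:
                candidates.append(rule)

    # deduplicate while preserving order
    seen = set()
    unique = []
    for cand in candidates:
        key = json.dumps(cand.to_dict(), sort_keys=True, default=str)
        if key not in seen:
            seen.add(key)
            unique.append(cand)
    return unique


def _graded_adjustment(rule, schema: effects.CovariateSchema) -> tuple[str, ...]:
    """Adjustment set graded by the rule's deepest domain.

    Spatial areas: calendar only.  Rules touching only environmental
    covariates: calendar; household: calendar + environmental; individual/
    birth: calendar + environmental + household.
    """
    if isinstance(rule, SpatialRule):
        return (schema.calendar,)
    deepest = 0
    for col, _ in rule.conditions:
        dom = schema.domains.get(col)
        if dom is None:
            raise KeyError(f"rule references unknown covariate {col!r}")
        depth = {"environmental": 1, "household": 2, "individual": 3}[dom]
        deepest = max(deepest, depth)
    out = [schema.calendar]
    rule_cols = {c for c, _ in rule.conditions}
    if deepest >= 2:
        out.extend(n for n in schema.in_domain("environmental") if n not in rule_cols)
    if deepest >= 3:
        out.extend(n for n in schema.in_domain("household") if n not in rule_cols)
    return tuple(out)


@dataclass
class SummaryRow:
    rule: str
    provenance: str
    n_hyp: int
    prevalence_hyp: float
    n_val: int
    prevalence_val: float
    suppressed: bool
    risk_in_hyp: float | None = None
    risk_out_hyp: float | None = None
    synergy_hyp: EffectEstimate | None = None
    tmle_hyp: EffectEstimate | None = None
    risk_in_val: float | None = None
    risk_out_val: float | None = None
    synergy_val: EffectEstimate | None = None
    tmle_val: EffectEstimate | None = None
    similarity_p: float | None = None
    combined: EffectEstimate | None = None
    paf_percent: float | None = None


def validate_candidates(
    rules: Sequence[Rule | SpatialRule],
    wc_hyp: WeightedCohort,
    wc_val: WeightedCohort,
    schema: effects.CovariateSchema,
    study: StudyConfig,
    discovery_digest: str | None = None,
) -> list[SummaryRow]:
    """Score frozen candidate rules on both cohorts (Table-1-style summary)."""
    if discovery_digest is not None and rules_digest(rules) != discovery_digest:
        raise ValueError("candidate rules do not match the frozen discovery artifact")

    risk_hyp = float(
        np.sum(wc_hyp.weights * wc_hyp.data["died"].to_numpy()) / wc_hyp.weighted_n
    ) * 100.0
    risk_val = float(
        np.sum(wc_val.weights * wc_val.data["died"].to_numpy()) / wc_val.weighted_n
    ) * 100.0
    overall_risk = weights.pooled_overall_risk(
        [risk_hyp, risk_val], [wc_hyp.weighted_n, wc_val.weighted_n]
    )

    out: list[SummaryRow] = []
    for rule in rules:
        mask_hyp = np.asarray(rule(wc_hyp.data), dtype=bool)
        mask_val = np.asarray(rule(wc_val.data), dtype=bool)
        n_h, n_v = int(mask_hyp.sum()), int(mask_val.sum())
        cells = [
            n_h, len(mask_hyp) - n_h,
            n_v, len(mask_val) - n_v,
        ]
        row = SummaryRow(
            rule=rule.describe(),
            provenance=rule.provenance,
            n_hyp=n_h,
            prevalence_hyp=n_h / len(mask_hyp),
            n_val=n_v,
            prevalence_val=n_v / len(mask_val),
            suppressed=min(cells) < study.few_children_threshold,
        )
        if row.suppressed:  # "very few children"
            out.append(row)
            continue
        adj = _graded_adjustment(rule, schema)
        in_h, out_h = weights.crude_risk(wc_hyp, mask_hyp)
        in_v, out_v = weights.crude_risk(wc_val, mask_val)
        row.risk_in_hyp, row.risk_out_hyp = in_h.risk, out_h.risk
        row.risk_in_val, row.risk_out_val = in_v.risk, out_v.risk
        if len(rule.components) >= 2:
            row.synergy_hyp = weights.synergy_statistic(wc_hyp, rule.components, schema.calendar)
            row.synergy_val = weights.synergy_statistic(wc_val, rule.components, schema.calendar)
        est_h, _ = effects.tmle_risk_difference(wc_hyp, mask_hyp, adj, calendar=schema.calendar)
        est_v, _ = effects.tmle_risk_difference(wc_val, mask_val, adj, calendar=schema.calendar)
        row.tmle_hyp = dataclasses.replace(est_h, cohort_tag="hypothesis")
        row.tmle_val = dataclasses.replace(est_v, cohort_tag="validation")
        row.similarity_p = effects.similarity_test(row.tmle_hyp, row.tmle_val)
        combined, _ = effects.combined_estimate(
            wc_hyp, wc_val, rule, adj, calendar=schema.calendar
        )
        row.combined = combined
        prevalence = (n_h + n_v) / (len(mask_hyp) + len(mask_val))
        row.paf_percent = weights.paf(prevalence, combined.estimate, overall_risk)
        out.append(row)
    return out


def summary_to_frame(rows: Sequence[SummaryRow]) -> pd.DataFrame:
    def fmt(e: EffectEstimate | None, what: str):
        if e is None:
            return np.nan
        return {"est": e.estimate, "lo": e.ci_low, "hi": e.ci_high}[what]

    return pd.DataFrame(
        {
            "rule": [r.rule for r in rows],
            "provenance": [r.provenance for r in rows],
            "n_hypothesis": [r.n_hyp for r in rows],
            "prevalence_hypothesis": [r.prevalence_hyp for r in rows],
            "n_validation": [r.n_val for r in rows],
            "prevalence_validation": [r.prevalence_val for r in rows],
            "very_few_children": [r.suppressed for r in rows],
            "crude_risk_in_hypothesis": [r.risk_in_hyp for r in rows],
            "crude_risk_out_hypothesis": [r.risk_out_hyp for r in rows],
            "crude_risk_in_validation": [r.risk_in_val for r in rows],
            "crude_risk_out_validation": [r.risk_out_val for r in rows],
            "synergy_hypothesis": [fmt(r.synergy_hyp, "est") for r in rows],
            "synergy_validation": [fmt(r.synergy_val, "est") for r in rows],
            "tmle_amrd_hypothesis": [fmt(r.tmle_hyp, "est") for r in rows],
            "tmle_amrd_hypothesis_lo": [fmt(r.tmle_hyp, "lo") for r in rows],
            "tmle_amrd_hypothesis_hi": [fmt(r.tmle_hyp, "hi") for r in rows],
            "tmle_amrd_validation": [fmt(r.tmle_val, "est") for r in rows],
            "tmle_amrd_validation_lo": [fmt(r.tmle_val, "lo") for r in rows],
            "tmle_amrd_validation_hi": [fmt(r.tmle_val, "hi") for r in rows],
            "similarity_p": [r.similarity_p for r in rows],
            "combined_amrd": [fmt(r.combined, "est") for r in rows],
            "combined_amrd_lo": [fmt(r.combined, "lo") for r in rows],
            "combined_amrd_hi": [fmt(r.combined, "hi") for r in rows],
            "paf_percent": [r.paf_percent for r in rows],
        }
    )
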