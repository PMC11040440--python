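"""Subgroup predicates shared by the discovery and validation stages.

A Rule is a conjunction of (column, value) conditions over cohort columns;
a SpatialRule is residence inside a circle.  Both evaluate to a boolean
membership mask on a cohort table, serialize to JSON, and carry the
provenance of the analysis that proposed them (spatial scan, single-factor
screen, or Causes of Outcome Learning).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Rule:
    """Conjunction of covariate conditions, e.g. twin AND birth_season=rainy."""

    conditions: tuple[tuple[str, object], ...]
    provenance: str = ""
    detail: dict = field(default_factory=dict, compare=False)

    def __call__(self, table: pd.DataFrame) -> np.ndarray:
        mask = np.ones(len(table), dtype=bool)
        for col, value in self.conditions:
            if col not in table.columns:
                raise KeyError(f"rule references unknown covariate {col!r}")
            if isinstance(value, (int, float)) and not isinstance(value, bool):
                mask &= table[col].to_numpy(dtype=float) == float(value)
            else:
                mask &= table[col].astype(str).to_numpy() == str(value)
        return mask

    @property
    def components(self) -> tuple[str, ...]:
        """Indicator specs for the synergy model (binary col or col=level)."""
        out = []
        for col, value in self.conditions:
            if value == 1 or value == 1.0:
                out.append(col)
            else:
                out.append(f"{col}={value}")
        return tuple(out)

    def describe(self) -> str:
        return " AND ".join(
            col if value in (1, 1.0) else f"{col}={value}" for col, value in self.conditions
        )

    def to_dict(self) -> dict:
        return {
            "kind": "rule",
            "conditions": [[c, v] for c, v in self.conditions],
            "provenance": self.provenance,
            "detail": self.detail,
        }


@dataclass(frozen=True)
class SpatialRule:
    """Residence within `radius` meters of a center point."""

    center: tuple[float, float]
    radius: float
    provenance: str = "spatial"
    detail: dict = field(default_factory=dict, compare=False)

    def __call__(self, table: pd.DataFrame) -> np.ndarray:
        cx, cy = self.center
        d2 = (table["x"].to_numpy(dtype=float) - cx) ** 2 + (
            table["y"].to_numpy(dtype=float) - cy
        ) ** 2
        return d2 <= self.radius**2

    @property
    def components(self) -> tuple[str, ...]:
        return ()

    def describe(self) -> str:
        return f"within {self.radius:g} m of ({self.center[0]:g}, {self.center[1]:g})"

    def to_dict(self) -> dict:
        return {
            "kind": "spatial",
            "center": list(self.center),
            "radius": self.radius,
            "provenance": self.provenance,
            "detail": self.detail,
        }


def rule_from_dict(d: dict) -> Rule | SpatialRule:
    if d["kind"] == "rule":
        return Rule(
            conditions=tuple((c, v) for c, v in d["conditions"]),
            provenance=d.get("provenance", ""),
            detail=d.get("detail", {}),
        )
    if d["kind"] == "spatial":
        return SpatialRule(
            center=tuple(d["center"]),
            radius=float(d["radius"]),
            provenance=d.get("provenance", "spatial"),
            detail=d.get("detail", {}),
        )
    raise ValueError(f"unknown rule kind {d['kind']!r}")


def rules_digest(rules: Sequence[Rule | SpatialRule]) -> str:
    """Content hash freezing a candidate list before validation."""
    payload = json.dumps([r.to_dict() for r in rules], sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def save_rules(rules: Sequence[Rule | SpatialRule], path) -> str:
    digest = rules_digest(rules)
    payload = {"digest": digest, "rules": [r.to_dict() for r in rules]}
    from pathlib import Path

    Path(path).write_text(json.dumps(payload, indent=2))
    return digest


def load_rules(path, expected_digest: str | None = None):
    from pathlib import Path

    payload = json.loads(Path(path).read_text())
    rules = [rule_from_dict(d) for d in payload["rules"]]
    digest = rules_digest(rules)
    if digest != payload.get("digest"):
        raise ValueError("rule artifact digest mismatch: candidates were modified")
    if expected_digest is not None and digest != expected_digest:
        raise ValueError("rule artifact does not match the expected discovery digest")
    return rules, digest
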