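"""Causes of Outcome Learning: non-negative risk decomposition and clustering.

A one-hidden-layer network constrained so it can only *add* risk above a
baseline intercept:

    p_i = clamp( R_b + sum_h w2_h * relu( sum_f W1_fh x_if + b_h ), 0, 1 )

with W1 >= 0, w2 >= 0 and hidden biases b <= 0.  Hidden units therefore act
as soft AND gates ("synergy units"): a unit only fires once enough of its
input features are present to overcome its negative bias, which is what
makes the model sensitive to interactions in subpopulations rather than
population-average main effects.  Calendar time enters as birth-year band
indicators so period effects are absorbed by the network instead of
confounding the covariate contributions.

Each child's predicted excess risk is decomposed into per-feature risk
contributions by attributing every hidden unit's output to its active
features proportionally to their share of the positive pre-activation.  The
decomposition is complete by construction: baseline + contributions
(+ clamp residual) equals the prediction exactly.  Children are then
clustered on their contribution profiles (Ward linkage) and each cluster is
summarized as a conjunction rule over its defining features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .rules import Rule


@dataclass
class CoolDesign:
    """Binary design matrix (one-hot, reference levels dropped) plus outcome."""

    X: np.ndarray              # (n, F) in {0, 1}
    y: np.ndarray              # (n,) in {0, 1}
    weights: np.ndarray        # (n,) IPCW weights
    feature_names: tuple[str, ...]
    # feature name -> (column, value) for decoding back to cohort columns
    feature_meta: dict = field(default_factory=dict)
    child_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")
        if not np.isin(self.X, (0.0, 1.0)).all():
            raise ValueError("design entries must be 0/1")


DEFAULT_YEAR_BAND_WIDTH = 3


def encode_features(
    cohort: pd.DataFrame,
    binary: Sequence[str] = (),
    categorical: Sequence[str] = (),
    weights: np.ndarray | None = None,
    year_band_width: int = DEFAULT_YEAR_BAND_WIDTH,
    calendar: str | None = "birth_year",
) -> CoolDesign:
    """One-hot encode covariates; calendar time becomes birth-year bands.

    Reference levels (the alphabetically first) are dropped.  Constant
    columns are dropped with a warning rather than passed to the model.
    """
    import warnings

    cols: dict[str, np.ndarray] = {}
    meta: dict[str, tuple[str, object]] = {}
    for name in binary:
        v = cohort[name].to_numpy(dtype=float)
        if v.min() == v.max():
            warnings.warn(f"dropping constant column {name!r}")
            continue
        cols[name] = v
        meta[name] = (name, 1)
    for name in categorical:
        levels = sorted(cohort[name].astype(str).unique())
        if len(levels) < 2:
            warnings.warn(f"dropping constant column {name!r}")
            continue
        for level in levels[1:]:  # reference = first level
            key = f"{name}={level}"
            cols[key] = (cohort[name].astype(str) == level).to_numpy(dtype=float)
            meta[key] = (name, level)
    if calendar is not None and calendar in cohort.columns:
        years = cohort[calendar].to_numpy(dtype=int)
        y0 = int(years.min())
        bands = (years - y0) // year_band_width
        for band in sorted(np.unique(bands))[1:]:
            lo = y0 + band * year_band_width
            hi = lo + year_band_width - 1
            key = f"{calendar}_band={lo}-{hi}"
            cols[key] = (bands == band).astype(float)
            meta[key] = (f"__band__{calendar}", (int(lo), int(hi)))
    if not cols:
        raise ValueError("no usable features")
    names = tuple(cols)
    X = np.column_stack([cols[n] for n in names])
    y = cohort["died"].to_numpy(dtype=float)
    w = np.ones(len(cohort)) if weights is None else np.asarray(weights, dtype=float)
    ids = cohort["child_id"].to_numpy() if "child_id" in cohort.columns else None
    return CoolDesign(X=X, y=y, weights=w, feature_names=names, feature_meta=meta, child_ids=ids)


def decode_row(design: CoolDesign, row: int) -> dict:
    """Reconstruct the original covariate values for one child (encoder inverse)."""
    out: dict = {}
    x = design.X[row]
    by_column: dict[str, list] = {}
    for j, name in enumerate(design.feature_names):
        col, value = design.feature_meta[name]
        by_column.setdefault(col, []).append((value, x[j]))
    for col, pairs in by_column.items():
        if col.startswith("__band__"):
            continue
        active = [v for v, on in pairs if on == 1.0]
        if len(pairs) == 1 and pairs[0][0] == 1:  # binary column
            out[col] = int(pairs[0][1])
        elif active:
            out[col] = active[0]
        else:
            out[col] = "__reference__"
    return out


@dataclass(frozen=True)
class CoolHyperparams:
    hidden: int = 10
    learning_rate: float = 0.01   # Adam step size
    epochs: int = 400
    restarts: int = 10
    seed: int = 0
    init_scale: float = 0.05
    tol: float = 1e-9             # relative loss-change stopping rule
    patience: int = 25


@dataclass
class CoolModel:
    W1: np.ndarray        # (F, H) >= 0
    b: np.ndarray         # (H,) <= 0
    w2: np.ndarray        # (H,) >= 0
    baseline: float       # R_b in [0, 1]
    hyperparams: CoolHyperparams
    feature_names: tuple[str, ...]
    loss_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    restart_losses: tuple[float, ...] = ()

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(predicted risk clamped to [0,1], hidden relu activations)."""
        act = np.maximum(X @ self.W1 + self.b, 0.0)
        raw = self.baseline + act @ self.w2
        return np.clip(raw, 0.0, 1.0), act

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "W1": self.W1.tolist(),
            "b": self.b.tolist(),
            "w2": self.w2.tolist(),
            "baseline": self.baseline,
            "feature_names": list(self.feature_names),
            "hyperparams": self.hyperparams.__dict__,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _train_once(X, y, w, hp: CoolHyperparams, rng: np.random.Generator):
    n, F = X.shape
    H = hp.hidden
    W1 = np.abs(rng.normal(0.0, hp.init_scale, (F, H)))
    b = -np.abs(rng.normal(0.0, hp.init_scale, H))
    w2 = np.full(H, hp.init_scale)
    Rb = float(np.average(y, weights=w))
    wsum = w.sum()

    params = [W1, b, w2]
    m = [np.zeros_like(p) for p in params] + [0.0]
    v = [np.zeros_like(p) for p in params] + [0.0]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    losses = np.empty(hp.epochs)
    best_loss = np.inf
    stall = 0
    for t in range(hp.epochs):
        z = X @ W1 + b
        act = np.maximum(z, 0.0)
        raw = Rb + act @ w2
        p = np.clip(raw, 0.0, 1.0)
        resid = p - y
        losses[t] = float(np.sum(w * resid**2) / wsum)

        live = ((raw > 0.0) & (raw < 1.0)) | ((raw <= 0.0) & (resid < 0)) | (
            (raw >= 1.0) & (resid > 0)
        )
        e = (2.0 / wsum) * w * resid * live  # dL/draw
        g_w2 = act.T @ e
        d_act = np.outer(e, w2)
        d_z = d_act * (z > 0.0)
        g_W1 = X.T @ d_z
        g_b = d_z.sum(axis=0)
        g_Rb = float(e.sum())

        grads = [g_W1, g_b, g_w2, g_Rb]
        new = []
        for k, (par, g) in enumerate(zip([W1, b, w2, Rb], grads)):
            m[k] = beta1 * m[k] + (1 - beta1) * g
            v[k] = beta2 * v[k] + (1 - beta2) * (g * g if k < 3 else g**2)
            mhat = m[k] / (1 - beta1 ** (t + 1))
            vhat = v[k] / (1 - beta2 ** (t + 1))
            new.append(par - hp.learning_rate * mhat / (np.sqrt(vhat) + eps))
        W1 = np.maximum(new[0], 0.0)
        b = np.minimum(new[1], 0.0)
        w2 = np.maximum(new[2], 0.0)
        Rb = float(np.clip(new[3], 0.0, 1.0))

        if not np.isfinite(losses[t]):
            raise FloatingPointError(
                "training diverged (loss is not finite); lower the learning rate"
            )
        if losses[t] < best_loss * (1.0 - hp.tol):
            best_loss = losses[t]
            stall = 0
        else:
            stall += 1
            if stall >= hp.patience:
                losses = losses[: t + 1]
                break
    return (W1, b, w2, Rb), losses


def train_cool(design: CoolDesign, hyperparams: CoolHyperparams | None = None) -> CoolModel:
    """Fit the non-negative network by projected Adam; best of `restarts` inits.

    Minimizes the weighted squared error; after every step negative entries
    of W1 and w2 are projected to 0, biases capped at 0 and the baseline
    clamped to [0, 1].  Bit-reproducible given (data, hyperparams, seed).
    """
    hp = hyperparams or CoolHyperparams()
    n, F = design.X.shape
    if design.y.min() == design.y.max():
        raise ValueError("outcome must contain both classes")
    if n < 10 * hp.hidden:
        raise ValueError(f"need n >= 10*hidden = {10 * hp.hidden} children, got {n}")
    master = np.random.default_rng(hp.seed)
    best = None
    restart_losses = []
    for _ in range(max(1, hp.restarts)):
        rng = np.random.default_rng(master.integers(2**31))
        params, losses = _train_once(design.X, design.y, design.weights, hp, rng)
        restart_losses.append(float(losses[-1]))
        if best is None or losses[-1] < best[1][-1]:
            best = (params, losses)
    (W1, b, w2, Rb), losses = best
    return CoolModel(
        W1=W1,
        b=b,
        w2=w2,
        baseline=Rb,
        hyperparams=hp,
        feature_names=design.feature_names,
        loss_trace=losses,
        restart_losses=tuple(restart_losses),
    )


@dataclass
class ContributionProfile:
    """Per-child per-feature risk contributions; complete by construction."""

    baseline: float
    contributions: np.ndarray   # (n, F) >= 0
    clamp_residual: np.ndarray  # (n,) prediction minus (baseline + sum of contributions)
    predictions: np.ndarray     # (n,)
    feature_names: tuple[str, ...]
    child_ids: np.ndarray | None = None

    def total_excess(self) -> np.ndarray:
        return self.contributions.sum(axis=1)


def risk_contributions(model: CoolModel, design: CoolDesign) -> ContributionProfile:
    """Attribute each hidden unit's output to its active features.

    c_if = sum_h w2_h * relu_h * (W1_fh x_if / sum_f' W1_f'h x_if').  A unit
    with positive relu output necessarily has a positive pre-activation sum
    (biases are <= 0), so the share is well defined.
    """
    if model.feature_names != design.feature_names:
        raise ValueError("model and design feature names do not match")
    X = design.X
    pos = X @ model.W1                       # (n, H) positive pre-activation sums
    act = np.maximum(pos + model.b, 0.0)
    assert not np.any((act > 0) & (pos <= 0)), "active unit with zero pre-activation"
    unit_out = act * model.w2                # (n, H)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(pos > 0, unit_out / pos, 0.0)
    contrib = (share @ model.W1.T) * X       # (n, F)
    raw = model.baseline + unit_out.sum(axis=1)
    pred = np.clip(raw, 0.0, 1.0)
    residual = pred - (model.baseline + contrib.sum(axis=1))
    return ContributionProfile(
        baseline=model.baseline,
        contributions=contrib,
        clamp_residual=residual,
        predictions=pred,
        feature_names=design.feature_names,
        child_ids=design.child_ids,
    )


@dataclass
class SubgroupSummary:
    label: int
    n: int
    prevalence: float
    weighted_mean_risk: float     # observed, per-100
    mean_contributions: np.ndarray
    flagged_small: bool


@dataclass
class SubgroupResult:
    assignments: np.ndarray       # (n,) cluster labels starting at 0
    groups: list[SubgroupSummary]
    linkage_matrix: np.ndarray | None
    feature_names: tuple[str, ...]


def _weighted_ward_linkage(points: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Ward agglomeration of multiplicity-weighted points.

    Equivalent to Ward linkage on the full data set with each row replicated
    `sizes` times (identical rows always merge first at zero cost), but runs
    on the deduplicated profiles.  Returns a scipy-style merge table
    [id_i, id_j, height, merged_size]; heights are monotone Ward merge costs.
    """
    m = points.shape[0]
    total = 2 * m - 1
    cent = np.zeros((total, points.shape[1]))
    cent[:m] = points
    n = np.zeros(total)
    n[:m] = sizes
    active = np.zeros(total, dtype=bool)
    active[:m] = True
    # pairwise Ward merge costs among active clusters
    cost = np.full((total, total), np.inf)

    def _costs_to(i, idx):
        d2 = ((cent[idx] - cent[i]) ** 2).sum(axis=1)
        return n[idx] * n[i] / (n[idx] + n[i]) * d2

    idx0 = np.arange(m)
    for i in range(m):
        others = idx0[i + 1:]
        if others.size:
            cost[i, others] = _costs_to(i, others)

    Z = np.zeros((m - 1, 4))
    for step in range(m - 1):
        flat = np.argmin(cost[:m + step, : m + step])
        i, j = divmod(int(flat), m + step)
        new = m + step
        Z[step] = (i, j, np.sqrt(max(cost[i, j], 0.0)), n[i] + n[j])
        cent[new] = (n[i] * cent[i] + n[j] * cent[j]) / (n[i] + n[j])
        n[new] = n[i] + n[j]
        active[i] = active[j] = False
        active[new] = True
        cost[i, :] = np.inf
        cost[:, i] = np.inf
        cost[j, :] = np.inf
        cost[:, j] = np.inf
        live = np.flatnonzero(active[:new])
        if live.size:
            cost[live, new] = _costs_to(new, live)
    return Z


def _cut_merges(Z: np.ndarray, m: int, n_clusters: int) -> np.ndarray:
    """Labels for the partition obtained after m - n_clusters merges."""
    parent = np.arange(2 * m - 1)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for step in range(m - n_clusters):
        i, j = int(Z[step, 0]), int(Z[step, 1])
        parent[find(i)] = parent[find(j)] = m + step
    roots = np.array([find(i) for i in range(m)])
    _, labels = np.unique(roots, return_inverse=True)
    return labels


def extract_subgroups(
    profile: ContributionProfile,
    design: CoolDesign,
    max_groups: int = 8,
    min_prevalence: float = 0.005,
    round_decimals: int = 6,
) -> SubgroupResult:
    """Cluster contribution profiles (Ward/Euclidean) into candidate subgroups.

    Ward linkage runs on the deduplicated (rounded) profiles weighted by
    their multiplicities, which is exactly Ward on the full cohort — binary
    inputs make profiles heavily repeated, so this scales to large cohorts.
    Groups below `min_prevalence` are kept but flagged "very few children".
    """
    if max_groups < 1:
        raise ValueError("max_groups must be >= 1")
    C = np.round(profile.contributions, round_decimals)
    uniq, inverse, counts = np.unique(C, axis=0, return_inverse=True, return_counts=True)
    if uniq.shape[0] == 1 or max_groups == 1:
        assignments = np.zeros(C.shape[0], dtype=int)
        Z = None
    else:
        Z = _weighted_ward_linkage(uniq, counts.astype(float))
        labels_u = _cut_merges(Z, uniq.shape[0], min(max_groups, uniq.shape[0]))
        assignments = labels_u[inverse]
    n = C.shape[0]
    y = design.y
    w = design.weights
    groups = []
    for lab in np.unique(assignments):
        mask = assignments == lab
        prev = mask.mean()
        risk = float(np.sum(w[mask] * y[mask]) / np.sum(w[mask])) * 100.0
        groups.append(
            SubgroupSummary(
                label=int(lab),
                n=int(mask.sum()),
                prevalence=float(prev),
                weighted_mean_risk=risk,
                mean_contributions=profile.contributions[mask].mean(axis=0),
                flagged_small=prev < min_prevalence,
            )
        )
    groups.sort(key=lambda g: g.weighted_mean_risk, reverse=True)
    return SubgroupResult(
        assignments=assignments,
        groups=groups,
        linkage_matrix=Z,
        feature_names=design.feature_names,
    )


def subgroup_to_rule(
    result: SubgroupResult,
    label: int,
    design: CoolDesign,
    threshold: float = 0.5,
) -> Rule:
    """Summarize a cluster as a conjunction of its defining features.

    Features whose group-mean contribution reaches `threshold` times the
    group's top contribution define the rule; at threshold >= 1 ties at the
    top are broken alphabetically so the rule is a single deterministic
    feature.  Calendar-band features never define a rule.
    """
    group = next((g for g in result.groups if g.label == label), None)
    if group is None or group.n == 0:
        raise ValueError(f"group {label} is empty or unknown")
    mask = result.assignments == label
    activity = design.X[mask].max(axis=0)
    eligible = [
        (name, group.mean_contributions[j])
        for j, name in enumerate(result.feature_names)
        if activity[j] > 0 and not design.feature_meta[name][0].startswith("__band__")
    ]
    if not eligible:
        raise ValueError("no defining features: group has no active features")
    top = max(c for _, c in eligible)
    if top <= 0:
        raise ValueError("no defining features: all contributions are zero")
    if threshold >= 1.0:
        winners = sorted(name for name, c in eligible if c == top)
        names = [winners[0]]
    else:
        names = [name for name, c in eligible if c >= threshold * top]
    conditions = tuple(design.feature_meta[n] for n in sorted(names))
    return Rule(conditions=conditions, provenance="cool", detail={"group": int(label)})


def save_heatmap(result: SubgroupResult, path: str | Path) -> None:
    """Group x feature mean-contribution heatmap (white = none, dark red = highest)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = np.vstack([g.mean_contributions for g in result.groups])
    fig, ax = plt.subplots(
        figsize=(max(6, 0.4 * mat.shape[1]), max(3, 0.4 * mat.shape[0]))
    )
    im = ax.imshow(mat, cmap="Reds", aspect="auto", vmin=0.0)
    ax.set_xticks(range(mat.shape[1]))
    ax.set_xticklabels(result.feature_names, rotation=90, fontsize=7)
    ax.set_yticks(range(mat.shape[0]))
    ax.set_yticklabels([f"group {g.label} (n={g.n})" for g in result.groups], fontsize=8)
    fig.colorbar(im, ax=ax, label="mean risk contribution")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_contributions(profile: ContributionProfile, path: str | Path) -> None:
    df = pd.DataFrame(profile.contributions, columns=list(profile.feature_names))
    if profile.child_ids is not None:
        df.insert(0, "child_id", profile.child_ids)
    df.to_csv(path, index=False)
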