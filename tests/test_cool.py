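"""Causes of Outcome Learning: encoding, training, decomposition, clustering."""

import numpy as np
import pandas as pd
import pytest

from riskgroups import cool
from riskgroups.cool import CoolHyperparams

from conftest import toy_outcome_frame


def _frame(seed=0, n=20_000, risk_fn=None, **prevalences):
    rng = np.random.default_rng(seed)
    cols = {name: rng.binomial(1, p, n) for name, p in prevalences.items()}
    risk = np.full(n, 0.05) if risk_fn is None else risk_fn(cols)
    y = rng.binomial(1, risk).astype(float)
    return toy_outcome_frame(y, **cols), cols


class TestEncoding:
    def test_binary_covariate_single_column(self):
        frame, _ = _frame(seed=1, n=200, a=0.5)
        d = cool.encode_features(frame, binary=["a"], calendar=None)
        assert d.feature_names == ("a",)

    def test_categorical_drops_reference(self):
        frame, _ = _frame(seed=2, n=500, a=0.5)
        rng = np.random.default_rng(0)
        frame["ethnicity"] = rng.choice(list("abcde"), 500)
        d = cool.encode_features(frame, categorical=["ethnicity"], calendar=None)
        assert len(d.feature_names) == 4
        assert all(name.startswith("ethnicity=") for name in d.feature_names)

    def test_calendar_becomes_year_bands(self):
        frame, _ = _frame(seed=3, n=500, a=0.5)
        frame["birth_year"] = np.random.default_rng(1).integers(2003, 2012, 500)
        d = cool.encode_features(frame, binary=["a"], year_band_width=3)
        bands = [n for n in d.feature_names if n.startswith("birth_year_band=")]
        assert len(bands) == 2  # 3 bands over 2003-2011, reference dropped

    def test_decode_roundtrips_original_values(self):
        frame, _ = _frame(seed=4, n=300, a=0.4, b=0.6)
        rng = np.random.default_rng(2)
        frame["eth"] = rng.choice(["x", "y", "z"], 300)
        d = cool.encode_features(frame, binary=["a", "b"], categorical=["eth"], calendar=None)
        for row in (0, 17, 299):
            decoded = cool.decode_row(d, row)
            assert decoded["a"] == frame.loc[row, "a"]
            assert decoded["b"] == frame.loc[row, "b"]
            expected = frame.loc[row, "eth"]
            assert decoded["eth"] == (expected if expected != "x" else "__reference__")

    def test_constant_column_dropped_with_warning(self):
        frame, _ = _frame(seed=5, n=100, a=0.5)
        frame["always"] = 1
        with pytest.warns(UserWarning, match="always"):
            d = cool.encode_features(frame, binary=["a", "always"], calendar=None)
        assert d.feature_names == ("a",)


FAST = CoolHyperparams(hidden=5, restarts=2, epochs=300, seed=0)


class TestTraining:
    def test_null_data_baseline_only(self):
        frame, _ = _frame(seed=6, a=0.2, b=0.5, c=0.7)
        d = cool.encode_features(frame, binary=["a", "b", "c"], calendar=None)
        model = cool.train_cool(d, FAST)
        se = np.sqrt(0.05 * 0.95 / len(frame))
        assert abs(model.baseline - frame["died"].mean()) < 3 * se + 0.005
        profile = cool.risk_contributions(model, d)
        assert profile.total_excess().mean() < 0.005

    def test_single_causal_feature_contribution(self):
        means = []
        for seed in range(10):
            frame, cols = _frame(
                seed=100 + seed,
                a=0.3,
                b=0.5,
                risk_fn=lambda c: 0.04 + 0.10 * c["a"],
            )
            d = cool.encode_features(frame, binary=["a", "b"], calendar=None)
            model = cool.train_cool(d, CoolHyperparams(hidden=5, restarts=2, epochs=300, seed=seed))
            profile = cool.risk_contributions(model, d)
            exposed = cols["a"] == 1
            means.append(profile.contributions[exposed, 0].mean())
        assert abs(np.mean(means) - 0.10) <= 0.02

    def test_same_seed_identical_model(self):
        frame, _ = _frame(seed=8, a=0.3)
        d = cool.encode_features(frame, binary=["a"], calendar=None)
        m1 = cool.train_cool(d, FAST)
        m2 = cool.train_cool(d, FAST)
        assert np.array_equal(m1.W1, m2.W1)
        assert np.array_equal(m1.w2, m2.w2)
        assert m1.baseline == m2.baseline

    def test_nonnegativity_after_training(self):
        frame, _ = _frame(seed=9, a=0.3, b=0.6, risk_fn=lambda c: 0.03 + 0.08 * c["a"] * c["b"])
        d = cool.encode_features(frame, binary=["a", "b"], calendar=None)
        model = cool.train_cool(d, FAST)
        assert (model.W1 >= 0).all() and (model.w2 >= 0).all() and (model.b <= 0).all()
        assert 0.0 <= model.baseline <= 1.0

    def test_single_class_outcome_rejected(self):
        frame, _ = _frame(seed=10, n=200, a=0.5, risk_fn=lambda c: np.zeros(200))
        d = cool.encode_features(frame, binary=["a"], calendar=None)
        with pytest.raises(ValueError, match="both classes"):
            cool.train_cool(d, FAST)


@pytest.fixture(scope="module")
def fitted():
    frame, cols = _frame(
        seed=11, a=0.3, b=0.5, risk_fn=lambda c: 0.03 + 0.09 * c["a"] * c["b"]
    )
    d = cool.encode_features(frame, binary=["a", "b"], calendar=None)
    model = cool.train_cool(d, FAST)
    return d, model, cols


class TestContributions:
    def test_decomposition_completeness_exact(self, fitted):
        d, model, _ = fitted
        profile = cool.risk_contributions(model, d)
        gap = np.abs(
            model.baseline
            + profile.contributions.sum(axis=1)
            + profile.clamp_residual
            - profile.predictions
        )
        assert gap.max() < 1e-10

    def test_all_zero_features_predict_baseline(self, fitted):
        d, model, _ = fitted
        zero = cool.CoolDesign(
            X=np.zeros((3, d.X.shape[1])),
            y=np.zeros(3),
            weights=np.ones(3),
            feature_names=d.feature_names,
            feature_meta=d.feature_meta,
        )
        profile = cool.risk_contributions(model, zero)
        assert np.all(profile.contributions == 0.0)
        assert np.allclose(profile.predictions, model.baseline)

    def test_single_active_feature_takes_all_excess(self, fitted):
        d, model, _ = fitted
        x = np.zeros((1, d.X.shape[1]))
        x[0, 0] = 1.0
        one = cool.CoolDesign(
            X=x, y=np.zeros(1), weights=np.ones(1),
            feature_names=d.feature_names, feature_meta=d.feature_meta,
        )
        profile = cool.risk_contributions(model, one)
        excess = profile.predictions[0] - model.baseline
        assert profile.contributions[0, 0] == pytest.approx(excess, abs=1e-12)
        assert np.all(profile.contributions[0, 1:] == 0.0)

    def test_inactive_features_contribute_nothing(self, fitted):
        d, model, _ = fitted
        profile = cool.risk_contributions(model, d)
        assert np.all(profile.contributions[d.X == 0.0] == 0.0)


class TestSubgroups:
    def test_two_planted_disjoint_groups_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        scores = []
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            n = 20_000
            u = rng.random(n)
            g1 = (u < 0.10).astype(int)
            g2 = ((u >= 0.10) & (u < 0.235)).astype(int)  # disjoint from g1
            y = rng.binomial(1, 0.03 + 0.10 * g1 + 0.08 * g2).astype(float)
            frame = toy_outcome_frame(y, g1=g1, g2=g2)
            d = cool.encode_features(frame, binary=["g1", "g2"], calendar=None)
            model = cool.train_cool(d, CoolHyperparams(hidden=5, restarts=2, epochs=300, seed=seed))
            profile = cool.risk_contributions(model, d)
            result = cool.extract_subgroups(profile, d, max_groups=3)
            truth = g1 + 2 * g2
            scores.append(adjusted_rand_score(truth, result.assignments))
        assert np.mean(np.asarray(scores) > 0.9) >= 0.9

    def test_all_zero_contributions_single_group(self):
        frame, _ = _frame(seed=12, n=1000, a=0.5)
        d = cool.encode_features(frame, binary=["a"], calendar=None)
        profile = cool.ContributionProfile(
            baseline=0.05,
            contributions=np.zeros((1000, 1)),
            clamp_residual=np.zeros(1000),
            predictions=np.full(1000, 0.05),
            feature_names=d.feature_names,
        )
        result = cool.extract_subgroups(profile, d, max_groups=5)
        assert len(result.groups) == 1
        assert np.all(result.assignments == 0)

    def test_small_group_flagged(self):
        frame, cols = _frame(
            seed=13, n=30_000, rare=0.002, risk_fn=lambda c: 0.03 + 0.20 * c["rare"]
        )
        d = cool.encode_features(frame, binary=["rare"], calendar=None)
        model = cool.train_cool(d, FAST)
        profile = cool.risk_contributions(model, d)
        result = cool.extract_subgroups(profile, d, max_groups=3, min_prevalence=0.005)
        small = [g for g in result.groups if g.prevalence < 0.005 and g.n > 0]
        assert small and all(g.flagged_small for g in small)

    def test_max_groups_validation(self):
        frame, _ = _frame(seed=14, n=1000, a=0.5)
        d = cool.encode_features(frame, binary=["a"], calendar=None)
        profile = cool.ContributionProfile(
            baseline=0.05,
            contributions=np.zeros((1000, 1)),
            clamp_residual=np.zeros(1000),
            predictions=np.full(1000, 0.05),
            feature_names=d.feature_names,
        )
        with pytest.raises(ValueError):
            cool.extract_subgroups(profile, d, max_groups=0)


@pytest.fixture(scope="module")
def synergy_fit():
    frame, cols = _frame(
        seed=15,
        n=50_000,
        twin=0.03,
        rainy=0.49,
        noise=0.3,
        risk_fn=lambda c: 0.03 + 0.10 * c["twin"] * c["rainy"],
    )
    d = cool.encode_features(frame, binary=["twin", "rainy", "noise"], calendar=None)
    model = cool.train_cool(d, CoolHyperparams(hidden=10, restarts=2, epochs=400, seed=3))
    profile = cool.risk_contributions(model, d)
    result = cool.extract_subgroups(profile, d, max_groups=5)
    return d, result


class TestRules:
    def test_planted_pair_rule(self, synergy_fit):
        d, result = synergy_fit
        rule = cool.subgroup_to_rule(result, result.groups[0].label, d, threshold=0.5)
        assert set(rule.components) == {"twin", "rainy"}

    def test_threshold_zero_includes_every_active_feature(self, synergy_fit):
        d, result = synergy_fit
        label = result.groups[0].label
        rule = cool.subgroup_to_rule(result, label, d, threshold=0.0)
        mask = result.assignments == label
        active = {
            name for j, name in enumerate(d.feature_names) if d.X[mask][:, j].max() > 0
        }
        assert set(rule.components) == active
        assert {"twin", "rainy"} <= active

    def test_threshold_one_single_feature_alphabetical_ties(self, synergy_fit):
        d, result = synergy_fit
        rule = cool.subgroup_to_rule(result, result.groups[0].label, d, threshold=1.0)
        assert len(rule.components) == 1

    def test_no_defining_features_errors(self, synergy_fit):
        d, result = synergy_fit
        background = result.groups[-1].label  # lowest-risk group: no contributions
        with pytest.raises(ValueError, match="no defining features"):
            cool.subgroup_to_rule(result, background, d, threshold=0.5)

    def test_rule_evaluates_on_cohort(self, synergy_fit):
        d, result = synergy_fit
        rule = cool.subgroup_to_rule(result, result.groups[0].label, d, threshold=0.5)
        frame = pd.DataFrame({"twin": [1, 1, 0], "rainy": [1, 0, 1], "noise": [0, 1, 0]})
        assert rule(frame).tolist() == [True, False, False]
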