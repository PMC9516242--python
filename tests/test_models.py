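import numpy as np
import pandas as pd
import pytest

from atherocytof.models import (
    DP,
    DPP,
    BalancedDataset,
    FeatureSet,
    StabilityParams,
    balance_groups,
    cutoff_analysis,
    decision_curve,
    evaluate_ensemble,
    roc_points,
    stability_select,
    train_ensemble,
)
from atherocytof.synthetic import generate_feature_cohort


# ---------------------------------------------------------------------------
# independent oracle: pairwise concordance AUC
# ---------------------------------------------------------------------------

def auc_pairwise(scores, labels):
    """AUC = P(random positive outranks random negative), ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestBalanceGroups:
    def test_13_vs_70_balanced_to_25(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"f": rng.normal(size=83)})
        y = np.array([0] * 13 + [1] * 70)
        bal = balance_groups(X, y, 25, seed=1)
        assert len(bal.y) == 50
        assert (bal.y == 0).sum() == 25 and (bal.y == 1).sum() == 25
        # minority rows all trace to the 13 originals, with replacement
        minority = bal.provenance[bal.provenance["label"] == 0]
        assert minority["resampled"].all()
        assert set(minority["original_index"]) <= set(range(13))
        # majority drawn without replacement
        majority = bal.provenance[bal.provenance["label"] == 1]
        assert not majority["resampled"].any()
        assert majority["original_index"].is_unique

    def test_already_balanced_preserves_rows(self):
        X = pd.DataFrame({"f": np.arange(50.0)})
        y = np.array([0] * 25 + [1] * 25)
        bal = balance_groups(X, y, 25, seed=2)
        assert sorted(bal.provenance["original_index"]) == list(range(50))

    def test_same_seed_identical_provenance(self):
        X = pd.DataFrame({"f": np.arange(30.0)})
        y = np.array([0] * 10 + [1] * 20)
        a = balance_groups(X, y, 15, seed=3)
        b = balance_groups(X, y, 15, seed=3)
        pd.testing.assert_frame_equal(a.provenance, b.provenance)

    def test_empty_class_rejected(self):
        X = pd.DataFrame({"f": np.arange(5.0)})
        with pytest.raises(ValueError):
            balance_groups(X, np.zeros(5, int), 3, seed=0)


class TestStabilitySelect:
    def test_dominant_feature_counted_every_repeat(self):
        """A feature that determines the label has importance > 0.04 in
        every repeat, hence count = n_repeats and selection."""
        rng = np.random.default_rng(1)
        n = 60
        y = np.array([0] * 30 + [1] * 30)
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
        X["signal"] = y * 10.0 + rng.normal(0, 0.1, n)
        params = StabilityParams(n_repeats=30, n_per_class=20, n_estimators=5)
        res = stability_select(X, y, params, seed=2)
        assert res.counts["signal"] == 30
        assert "signal" in res.selected

    def test_pure_noise_rarely_selected(self):
        """Null simulation at the cohort's geometry (47 cluster features,
        83-sample pool): selection counts stay far below the majority
        threshold and almost no feature is ever selected.  The 0.04
        importance cut sits meaningfully above uniform importance (1/47)
        only for universes of this size."""
        rng = np.random.default_rng(3)
        n_runs = 10
        total_selected = 0
        for r in range(n_runs):
            X = pd.DataFrame(
                rng.normal(size=(83, 47)), columns=[f"f{i}" for i in range(47)]
            )
            y = rng.permutation(np.array([0] * 40 + [1] * 43))
            params = StabilityParams(n_repeats=40, n_per_class=25, n_estimators=8)
            res = stability_select(X, y, params, seed=100 + r)
            total_selected += len(res.selected)
            # expected count per feature far below the majority threshold
            assert res.counts.mean() < 0.25 * params.n_repeats
        assert total_selected <= 4

    def test_constant_feature_never_selected(self):
        rng = np.random.default_rng(4)
        y = np.array([0] * 20 + [1] * 20)
        X = pd.DataFrame({
            "const": np.ones(40),
            "noise": rng.normal(size=40),
            "signal": y + rng.normal(0, 0.5, 40),
        })
        params = StabilityParams(n_repeats=20, n_per_class=15, n_estimators=5)
        res = stability_select(X, y, params, seed=5)
        assert res.counts["const"] == 0
        assert "const" not in res.selected

    def test_planted_features_recovered(self):
        immune, _, y, truth = generate_feature_cohort(seed=6)
        params = StabilityParams(n_repeats=100, n_per_class=15, n_estimators=5)
        res = stability_select(immune, y, params, seed=6)
        assert set(truth.informative_immune) <= set(res.selected)
        assert len(set(res.selected) - set(truth.informative_immune)) <= 1

    def test_monotone_in_effect_size(self):
        """Stronger planted effect never gives smaller selection counts for
        the planted features (in expectation over a few seeds)."""
        counts = {}
        for effect in (0.3, 1.8):
            totals = []
            for seed in range(3):
                immune, _, y, truth = generate_feature_cohort(
                    seed=seed, immune_effect=effect
                )
                params = StabilityParams(
                    n_repeats=40, n_per_class=15, n_estimators=4
                )
                res = stability_select(immune, y, params, seed=seed)
                totals.append(res.counts[truth.informative_immune].sum())
            counts[effect] = np.mean(totals)
        assert counts[1.8] > counts[0.3]

    def test_requires_two_classes_and_features(self):
        X = pd.DataFrame({"a": np.arange(10.0), "b": np.arange(10.0)})
        with pytest.raises(ValueError):
            stability_select(X, np.zeros(10, int), StabilityParams(n_repeats=1))
        with pytest.raises(ValueError):
            stability_select(
                X[["a"]], np.array([0] * 5 + [1] * 5), StabilityParams(n_repeats=1)
            )

    def test_count_threshold_default_is_majority(self):
        assert StabilityParams(n_repeats=1000).resolved_count_threshold() == 500


class TestTrainEnsemble:
    def test_separable_data_perfect_test_auc(self):
        rng = np.random.default_rng(7)
        y = np.array([0] * 30 + [1] * 30)
        X = pd.DataFrame({
            "f1": y * 5.0 + rng.normal(0, 0.1, 60),
            "f2": rng.normal(size=60),
        })
        ens = train_ensemble(X, y, seed=0, n_estimators=50, n_folds=10)
        _, auc = roc_points(ens.predict_proba(ens.X_test), ens.y_test)
        assert auc == 1.0

    def test_permutation_null_auc_centred(self):
        rng = np.random.default_rng(8)
        aucs = []
        for r in range(30):
            X = pd.DataFrame(
                rng.normal(size=(60, 8)), columns=[f"f{i}" for i in range(8)]
            )
            y = rng.permutation(np.array([0] * 30 + [1] * 30))
            ens = train_ensemble(X, y, seed=r, n_estimators=25, n_folds=10)
            _, auc = roc_points(ens.predict_proba(ens.X_test), ens.y_test)
            aucs.append(auc)
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_aggregation_identity_for_identical_models(self):
        rng = np.random.default_rng(9)
        y = np.array([0] * 25 + [1] * 25)
        X = pd.DataFrame({"f": y + rng.normal(0, 0.3, 50)})
        ens = train_ensemble(X, y, seed=1, n_estimators=20, n_folds=10)
        clone = ens.models[0]
        ens_same = type(ens)(
            models=[clone] * 10,
            feature_names=ens.feature_names,
            seed=0,
            X_test=ens.X_test,
            y_test=ens.y_test,
        )
        single = clone.predict_proba(ens.X_test.to_numpy())[:, 1]
        np.testing.assert_allclose(ens_same.predict_proba(ens.X_test), single)

    def test_bootstrap_balancing_of_training_set(self):
        rng = np.random.default_rng(10)
        y = np.array([0] * 13 + [1] * 70)
        X = pd.DataFrame({"f": y + rng.normal(0, 1, 83), "g": rng.normal(size=83)})
        ens = train_ensemble(
            X, y, seed=2, balance_train_to=50, n_estimators=20, n_folds=10
        )
        assert len(ens.models) == 10
        # test split untouched by balancing: still imbalanced originals
        assert len(ens.y_test) == 25

    def test_impossible_stratified_folds_rejected(self):
        X = pd.DataFrame({"f": np.arange(12.0)})
        y = np.array([0] * 6 + [1] * 6)
        with pytest.raises(ValueError, match="folds"):
            train_ensemble(X, y, seed=0, n_folds=10)


class TestRoc:
    def test_perfect_ranking(self):
        _, auc = roc_points([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_worked_example_075(self):
        scores = [0.9, 0.8, 0.7, 0.6]
        labels = [1, 0, 1, 0]
        _, auc = roc_points(scores, labels)
        assert auc == pytest.approx(auc_pairwise(scores, labels)) == 0.75

    def test_all_tied_scores_give_half(self):
        _, auc = roc_points([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_trapezoid_equals_pairwise_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(6, 40))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            # discretized scores so ties actually occur
            scores = rng.integers(0, 6, n) / 5.0
            _, auc = roc_points(scores, labels)
            assert auc == pytest.approx(auc_pairwise(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_points([0.1, 0.9], [1, 1])


class TestDecisionCurve:
    def test_all_negative_model_zero_benefit(self):
        out = decision_curve([0.0] * 10, [1, 0] * 5, thresholds=[0.2, 0.5, 0.8])
        assert (out["net_benefit"] == 0.0).all()

    def test_treat_all_closed_form(self):
        labels = [1] * 5 + [0] * 5  # prevalence 0.5
        out = decision_curve(np.linspace(0, 1, 10), labels, thresholds=[0.5])
        assert out["treat_all"].iloc[0] == pytest.approx(0.5 - 0.5 * 1.0) == 0.0

    def test_perfect_classifier_attains_prevalence_everywhere(self):
        labels = np.array([1] * 3 + [0] * 7)
        scores = labels.astype(float) * 0.99 + 0.005
        out = decision_curve(scores, labels)
        np.testing.assert_allclose(out["net_benefit"], 0.3, atol=1e-12)
        assert (out["net_benefit"] >= out["treat_all"] - 1e-12).all()

    def test_net_benefit_bounded_by_prevalence(self):
        rng = np.random.default_rng(12)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        out = decision_curve(scores, labels)
        assert (out["net_benefit"] <= labels.mean() + 1e-12).all()

    def test_threshold_bounds_enforced(self):
        with pytest.raises(ValueError):
            decision_curve([0.5], [1], thresholds=[1.0])


class TestCutoffAnalysis:
    def test_extreme_cutoffs(self):
        scores = np.array([0.2, 0.4, 0.6, 0.8])
        labels = np.array([0, 0, 1, 1])
        table, _ = cutoff_analysis(scores, labels, cutoffs=[1e-9, 0.5, 1 - 1e-9])
        lo, mid, hi = table.iloc[0], table.iloc[1], table.iloc[2]
        assert (lo["sensitivity"], lo["specificity"]) == (1.0, 0.0)
        assert (mid["sensitivity"], mid["specificity"]) == (1.0, 1.0)
        assert (hi["sensitivity"], hi["specificity"]) == (0.0, 1.0)

    def test_best_cutoff_maximizes_youden(self):
        scores = np.array([0.1, 0.3, 0.55, 0.7, 0.9])
        labels = np.array([0, 0, 1, 1, 1])
        table, best = cutoff_analysis(scores, labels, cutoffs=[0.2, 0.5, 0.8])
        assert best == 0.5
        assert table.loc[table["cutoff"] == 0.5, "youden_j"].iloc[0] == 1.0


class TestEvaluateEnsemble:
    def test_full_evaluation_surface(self):
        rng = np.random.default_rng(13)
        y = np.array([0] * 30 + [1] * 30)
        X = pd.DataFrame({
            "f": y * 2.0 + rng.normal(0, 1.0, 60),
            "g": rng.normal(size=60),
        })
        ens = train_ensemble(X, y, seed=3, n_estimators=30, n_folds=10)
        ev = evaluate_ensemble(ens)
        assert 0.0 <= ev.auc <= 1.0
        assert (np.diff(ev.roc["tpr"]) >= 0).all()  # ROC monotone
        assert 0.0 < ev.best_cutoff < 1.0
        assert len(ev.net_benefit) == 99

    def test_task_presets(self):
        assert DP.selection_n_per_class == 25
        assert DP.train_balance_to == 50
        assert DPP.selection_n_per_class == 15
        assert DPP.train_balance_to is None

    def test_feature_set_union(self):
        a = FeatureSet("immune", ("M02", "T05"))
        b = FeatureSet("clinical", ("age", "BMI"))
        c = FeatureSet.combined(a, b)
        assert c.names == ("M02", "T05", "age", "BMI")
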