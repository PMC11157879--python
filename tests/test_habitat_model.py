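"""Boosted use-availability model: metrics, thresholding, tuning, recovery."""

import numpy as np
import pandas as pd
import pytest

from movesdm.habitat_model import (DEFAULT_GRID, EvaluationError, GBMConfig,
                                   auc_score, evaluate, fit,
                                   iterative_variable_refit, kappa_score,
                                   partial_dependence, prevalence_threshold,
                                   simplify_covariates, split_train_test,
                                   tune)


def brute_force_auc(scores, labels):
    """Exhaustive pairwise concordance oracle (ties count one half)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def planted_frame(n=600, seed=0, noise_covs=3):
    """Labels driven by a logistic band response in 'bathy' plus 'sst'."""
    rng = np.random.default_rng(seed)
    bathy = rng.uniform(0, 3800, n)
    sst = rng.uniform(19, 28, n)
    eta = 6.0 * np.exp(-(((bathy - 700) / 400) ** 2)) + 4.0 * (sst - 19) / 9 - 4.0
    y = rng.random(n) < 1 / (1 + np.exp(-eta))
    data = {"bathy": bathy, "sst": sst, "label": y.astype(int)}
    for j in range(noise_covs):
        data[f"noise{j}"] = rng.normal(size=n)
    return pd.DataFrame(data)


class TestAUC:
    def test_matches_brute_force_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(10, 200))
            scores = np.round(rng.random(n), 2)     # force some ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert auc_score(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12)

    def test_known_four_point_case(self):
        # presences 0.9, 0.4; absences 0.6, 0.2 -> 3 of 4 pairs concordant
        assert auc_score([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.75

    def test_perfect_separation(self):
        assert auc_score([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            auc_score([0.1, 0.2], [1, 1])


class TestKappa:
    def test_closed_form_confusion_matrix(self):
        # TP=40, FN=10, FP=10, TN=40 -> po=0.8, pe=0.5 -> kappa 0.6
        scores = np.r_[np.full(40, 0.9), np.full(10, 0.1),
                       np.full(10, 0.9), np.full(40, 0.1)]
        labels = np.r_[np.ones(50), np.zeros(50)]
        assert kappa_score(scores, labels, 0.5) == pytest.approx(0.6)

    def test_perfect_agreement_is_one(self):
        scores = np.r_[np.full(20, 0.9), np.full(20, 0.1)]
        labels = np.r_[np.ones(20), np.zeros(20)]
        assert kappa_score(scores, labels, 0.5) == 1.0

    def test_random_labels_centre_on_zero(self):
        rng = np.random.default_rng(1)
        vals = []
        for _ in range(200):
            scores = rng.random(60)
            labels = rng.integers(0, 2, 60)
            vals.append(kappa_score(scores, labels, 0.5))
        assert abs(np.mean(vals)) < 0.05


class TestPrevalenceThreshold:
    def test_brute_force_optimality(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(12, 120))
            scores = np.round(rng.random(n), 2)
            labels = (rng.random(n) < 0.2).astype(int)
            if labels.min() == labels.max() or np.ptp(scores) == 0:
                continue
            t = prevalence_threshold(scores, labels)
            p_obs = labels.mean()
            err_t = abs((scores >= t).mean() - p_obs)
            best = min(abs((scores >= c).mean() - p_obs)
                       for c in np.unique(scores))
            assert err_t == pytest.approx(best, abs=1e-12)

    def test_one_in_six_design(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1, 0.1, 0.1])
        labels = np.array([1, 0, 0, 0, 0, 0])
        t = prevalence_threshold(scores, labels)
        assert 0.8 < t <= 0.9
        assert (scores >= t).mean() == pytest.approx(1 / 6)

    def test_symmetric_half_prevalence(self):
        scores = np.array([0.1, 0.3, 0.7, 0.9])
        labels = np.array([0, 0, 1, 1])
        t = prevalence_threshold(scores, labels)
        assert (scores >= t).mean() == 0.5

    def test_constant_scores_rejected(self):
        with pytest.raises(EvaluationError):
            prevalence_threshold(np.full(10, 0.4), [1] * 5 + [0] * 5)


class TestSplit:
    def test_quarter_held_out_stratified(self):
        frame = planted_frame(1000, seed=3)
        train, test = split_train_test(frame, 0.25, seed=0)
        assert len(test) == pytest.approx(250, abs=2)
        assert len(train) + len(test) == 1000
        assert len(np.intersect1d(train, test)) == 0
        y = frame["label"].to_numpy()
        assert 0 < y[test].mean() < 1 and 0 < y[train].mean() < 1

    def test_same_seed_same_partition(self):
        frame = planted_frame(200, seed=4)
        a = split_train_test(frame, 0.25, seed=9)
        b = split_train_test(frame, 0.25, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(EvaluationError):
            split_train_test(planted_frame(100), 0.0, seed=0)


class TestTune:
    def test_single_config_returned(self):
        frame = planted_frame(300, seed=5)
        cfg = GBMConfig(2, 50, 10, 0.1, 0.75)
        best, tab = tune(frame, ["bathy", "sst"], [cfg], seed=0)
        assert best == cfg and len(tab) == 1

    def test_underfit_config_loses(self):
        frame = planted_frame(800, seed=6)
        weak = GBMConfig(1, 5, 10, 0.05, 0.75)
        strong = GBMConfig(2, 200, 10, 0.1, 0.75)
        best, tab = tune(frame, ["bathy", "sst"], [weak, strong], seed=0)
        assert best == strong

    def test_every_combination_evaluated(self):
        frame = planted_frame(300, seed=7)
        grid = [GBMConfig(d, t, 10, s, 0.75)
                for d in (1, 2) for t in (20, 40) for s in (0.05, 0.1)]
        _, tab = tune(frame, ["bathy", "sst"], grid, seed=0)
        assert len(tab) == 8

    def test_default_grid_is_full_factorial(self):
        assert len(DEFAULT_GRID) == 3 * 3 * 2 * 2 * 2


class TestFitAndInfluence:
    def test_influence_sums_to_100(self):
        frame = planted_frame(400, seed=8)
        model = fit(frame, ["bathy", "sst", "noise0"], GBMConfig(2, 100, 10, 0.1, 0.75), 0)
        assert sum(model.relative_influence.values()) == pytest.approx(100.0, abs=1e-6)

    def test_planted_signal_recovery(self):
        # the two planted covariates should occupy the top two influence
        # ranks in nearly every seeded replicate
        hits = 0
        for seed in range(10):
            frame = planted_frame(700, seed=100 + seed)
            model = fit(frame, ["bathy", "sst", "noise0", "noise1", "noise2"],
                        GBMConfig(2, 150, 10, 0.1, 0.75), seed)
            top2 = sorted(model.relative_influence,
                          key=model.relative_influence.get)[-2:]
            hits += set(top2) == {"bathy", "sst"}
        assert hits >= 9

    def test_pure_noise_has_no_dominant_variable(self):
        rng = np.random.default_rng(9)
        hits = 0
        for seed in range(10):
            frame = planted_frame(400, seed=200 + seed)
            frame["label"] = rng.integers(0, 2, len(frame))
            model = fit(frame, ["bathy", "sst", "noise0", "noise1"],
                        GBMConfig(2, 100, 10, 0.1, 0.75), seed)
            hits += max(model.relative_influence.values()) < 60
        assert hits == 10

    def test_nonfinite_covariates_rejected(self):
        frame = planted_frame(100, seed=1)
        frame.loc[3, "bathy"] = np.nan
        with pytest.raises(ValueError):
            fit(frame, ["bathy", "sst"], GBMConfig(2, 50, 10, 0.1, 0.75), 0)


class TestEvaluateAndRefit:
    def test_heldout_recovery_metrics(self):
        frame = planted_frame(1200, seed=10)
        train, test = split_train_test(frame, 0.25, seed=0)
        model = fit(frame.iloc[train], ["bathy", "sst"],
                    GBMConfig(2, 200, 10, 0.1, 0.75), 0)
        m = evaluate(model, frame.iloc[test])
        assert m["global_auc"] > 0.8
        assert m["auc_ok"] and -1 <= m["global_kappa"] <= 1

    def test_passing_model_has_no_drops(self):
        frame = planted_frame(800, seed=11)
        model, metrics, audit = iterative_variable_refit(
            frame, ["bathy", "sst", "noise0"], GBMConfig(2, 150, 10, 0.1, 0.75),
            seed=0)
        assert metrics["global_auc"] > 0.6
        assert len(audit) == 1
        assert len(model.covariates) == 3

    def test_audit_trail_counts_fits(self):
        frame = planted_frame(400, seed=12)
        frame["label"] = np.random.default_rng(0).integers(0, 2, len(frame))
        model, metrics, audit = iterative_variable_refit(
            frame, ["bathy", "sst", "noise0", "noise1"],
            GBMConfig(1, 20, 10, 0.05, 0.75), min_auc=0.99, seed=0)
        # AUC floor unreachable on noise: drops until the 2-covariate floor
        assert len(model.covariates) == 2
        assert len(audit) == 3
        assert metrics.get("flagged")

    def test_simplification_drops_noise_keeps_signal(self):
        frame = planted_frame(900, seed=13)
        kept, trail = simplify_covariates(
            frame, ["bathy", "sst", "noise0", "noise1", "noise2"],
            GBMConfig(2, 150, 10, 0.1, 0.75), seed=0)
        assert "bathy" in kept
        assert len(kept) < 5


class TestPartialDependence:
    def test_monotone_planted_effect(self):
        from scipy.stats import spearmanr
        rng = np.random.default_rng(14)
        n = 800
        x = rng.uniform(0, 1, n)
        z = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(6 * x - 3.0)))).astype(int)
        frame = pd.DataFrame({"x": x, "z": z, "label": y})
        model = fit(frame, ["x", "z"], GBMConfig(2, 150, 10, 0.1, 0.75), 0)
        grid = np.linspace(0.05, 0.95, 15)
        curve = partial_dependence(model, frame, "x", grid)
        assert spearmanr(curve, grid).statistic > 0.9

    def test_unknown_covariate_rejected(self):
        frame = planted_frame(100, seed=15)
        model = fit(frame, ["bathy", "sst"], GBMConfig(1, 20, 10, 0.1, 0.75), 0)
        with pytest.raises(KeyError):
            partial_dependence(model, frame, "nope", np.array([0.0]))
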