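"""MAP classifier tests: fitting, Bayes-rule prediction, cross-validation,
metrics and shuffle chance."""

import numpy as np
import pandas as pd
import pytest

from whiskmap import (
    BehaviorPolicy,
    SimConfig,
    choice_consistency,
    classifier_performance,
    crossval_predict,
    fit_map_classifier,
    generate_session,
    predict,
    predict_mouse_choice,
    shuffle_chance,
)
from whiskmap.classifier import ClassifierFit


class TestFit:
    def test_balanced_labels_give_uniform_priors(self):
        X = pd.DataFrame({"x": ["a"] * 6})
        y = ["posterior", "middle", "anterior"] * 2
        fit = fit_map_classifier(X, y, {"x": "categorical"})
        assert np.allclose(fit.priors, 1 / 3)
        assert fit.classes == ["posterior", "middle", "anterior"]

    def test_predictor_identical_to_label_gives_identity_tables(self):
        y = ["posterior", "middle", "anterior"] * 3
        X = pd.DataFrame({"x": y})
        fit = fit_map_classifier(X, y, {"x": "categorical"})
        table = fit.conditionals["x"]["table"]
        levels = fit.conditionals["x"]["levels"]
        for k, cls in enumerate(fit.classes):
            assert table[k, levels.index(cls)] == 1.0

    def test_hand_enumerated_six_trial_tables(self):
        # class counts: posterior {a:2, b:1}; middle {a:1, b:2}
        X = pd.DataFrame({"x": ["a", "a", "b", "a", "b", "b"]})
        y = ["posterior"] * 3 + ["middle"] * 3
        fit = fit_map_classifier(X, y, {"x": "categorical"})
        lv = fit.conditionals["x"]["levels"]
        tab = fit.conditionals["x"]["table"]
        k_post = fit.classes.index("posterior")
        k_mid = fit.classes.index("middle")
        assert tab[k_post, lv.index("a")] == pytest.approx(2 / 3)
        assert tab[k_mid, lv.index("b")] == pytest.approx(2 / 3)
        assert np.allclose(fit.priors, 0.5)

    def test_gaussian_conditionals_recover_sample_moments(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0.0, 1.0, 50),
                            rng.normal(5.0, 2.0, 50)])
        y = ["posterior"] * 50 + ["middle"] * 50
        fit = fit_map_classifier(pd.DataFrame({"x": x}), y,
                                 {"x": "continuous"})
        g = fit.conditionals["x"]
        k = fit.classes.index("middle")
        assert g["mean"][k] == pytest.approx(x[50:].mean())
        assert g["sd"][k] == pytest.approx(x[50:].std(ddof=1))

    def test_absent_class_rejected(self):
        X = pd.DataFrame({"x": ["a", "b"]})
        with pytest.raises(ValueError):
            fit_map_classifier(X, [], {"x": "categorical"})


class TestPredict:
    def test_uniform_conditionals_fall_back_to_prior(self):
        fit = ClassifierFit(
            classes=["posterior", "middle"],
            priors=np.array([0.7, 0.3]),
            conditionals={"x": {"kind": "categorical", "levels": ["a", "b"],
                                "table": np.full((2, 2), 0.5)}},
            kinds={"x": "categorical"})
        labels, post = predict(fit, pd.DataFrame({"x": ["a", "b", "a"]}))
        assert list(labels) == ["posterior"] * 3
        assert np.allclose(post[:, 0], 0.7)

    def test_two_class_bayes_worked_example(self):
        # π=(.5,.5), P(x=1|y1)=.9, P(x=1|y2)=.2, observe x=1
        fit = ClassifierFit(
            classes=["y1", "y2"],
            priors=np.array([0.5, 0.5]),
            conditionals={"x": {"kind": "categorical", "levels": [0, 1],
                                "table": np.array([[0.1, 0.9], [0.8, 0.2]])}},
            kinds={"x": "categorical"})
        labels, post = predict(fit, pd.DataFrame({"x": [1]}))
        assert labels[0] == "y1"
        assert post[0, 0] == pytest.approx(0.45 / 0.55)
        assert post[0, 1] == pytest.approx(0.10 / 0.55)

    def test_posteriors_normalize(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.choice(["u", "v"], 40),
                          "b": rng.normal(0, 1, 40)})
        y = rng.choice(["posterior", "middle", "anterior"], 40)
        fit = fit_map_classifier(X, y, {"a": "categorical", "b": "continuous"})
        _, post = predict(fit, X)
        assert np.allclose(post.sum(axis=1), 1.0)

    def test_missing_value_raises(self):
        X = pd.DataFrame({"x": ["a", "b"]})
        y = ["posterior", "middle"]
        fit = fit_map_classifier(X, y, {"x": "categorical"})
        with pytest.raises(ValueError):
            predict(fit, pd.DataFrame({"x": [None]}))


class TestCrossValidation:
    def test_leave_one_out_limit(self):
        X = pd.DataFrame({"x": ["a", "a", "b", "b", "a", "b"]})
        y = ["posterior", "posterior", "middle", "middle", "posterior", "middle"]
        cv = crossval_predict(X, y, {"x": "categorical"}, k_folds=6,
                              rng=np.random.default_rng(0))
        assert classifier_performance(cv.predicted, y) == 1.0
        assert sorted(cv.fold) == list(range(6))

    def test_separable_predictor_classified_perfectly(self):
        rng = np.random.default_rng(0)
        y = list(rng.choice(["posterior", "middle", "anterior"], 120))
        X = pd.DataFrame({"x": y})
        cv = crossval_predict(X, y, {"x": "categorical"}, rng=rng)
        assert classifier_performance(cv.predicted, y) == 1.0

    def test_fixed_seed_reproduces_folds_and_predictions(self):
        rng1, rng2 = np.random.default_rng(9), np.random.default_rng(9)
        X = pd.DataFrame({"x": np.random.default_rng(3).normal(0, 1, 60)})
        y = list(np.random.default_rng(4).choice(["posterior", "middle"], 60))
        cv1 = crossval_predict(X, y, {"x": "continuous"}, rng=rng1)
        cv2 = crossval_predict(X, y, {"x": "continuous"}, rng=rng2)
        assert np.array_equal(cv1.fold, cv2.fold)
        assert np.array_equal(cv1.predicted, cv2.predicted)

    def test_every_trial_predicted_exactly_once(self):
        rng = np.random.default_rng(2)
        y = list(rng.choice(["posterior", "middle", "anterior"], 57))
        X = pd.DataFrame({"x": rng.normal(0, 1, 57)})
        cv = crossval_predict(X, y, {"x": "continuous"}, rng=rng)
        assert len(cv.predicted) == 57
        assert not any(p is None for p in cv.predicted)
        sizes = np.bincount(cv.fold)
        assert sizes.max() - sizes.min() <= 1


class TestMetrics:
    def test_performance_counting(self):
        assert classifier_performance(["a", "b", "c", "d"],
                                      ["a", "b", "c", "x"]) == 0.75
        assert classifier_performance(["a"], ["a"]) == 1.0
        assert classifier_performance(["a"], ["b"]) == 0.0
        with pytest.raises(ValueError):
            classifier_performance([], [])

    def test_performance_invariant_to_trial_reordering(self):
        rng = np.random.default_rng(0)
        pred = rng.choice(["a", "b"], 50)
        true = rng.choice(["a", "b"], 50)
        perm = rng.permutation(50)
        assert classifier_performance(pred, true) == \
            classifier_performance(pred[perm], true[perm])

    def test_choice_consistency_hand_count(self):
        pred_loc = ["posterior", "middle", "anterior",
                    "posterior", "middle", "anterior"]
        mouse = ["posterior", "middle", "middle",
                 "anterior", "middle", "anterior"]
        # identity mapping: matches on trials 0,1,4,5 -> 4/6
        assert choice_consistency(pred_loc, mouse) == pytest.approx(4 / 6)


class TestShuffleChance:
    def test_null_mean_near_one_third_for_balanced_labels(self):
        rng = np.random.default_rng(0)
        y = ["posterior", "middle", "anterior"] * 100
        X = pd.DataFrame({"x": rng.normal(0, 1, 300)})
        null = shuffle_chance(X, y, {"x": "continuous"}, iters=30, rng=rng)
        assert abs(null.mean - 1 / 3) < 0.05

    def test_informative_signal_exceeds_null_upper_bound(self):
        rng = np.random.default_rng(1)
        y = list(rng.choice(["posterior", "middle", "anterior"], 200))
        x = np.array([{"posterior": -2.0, "middle": 0.0,
                       "anterior": 2.0}[c] for c in y])
        X = pd.DataFrame({"x": x + rng.normal(0, 0.5, 200)})
        cv = crossval_predict(X, y, {"x": "continuous"}, rng=rng)
        perf = classifier_performance(cv.predicted, y)
        null = shuffle_chance(X, y, {"x": "continuous"}, iters=50, rng=rng)
        assert perf > null.hi

    def test_fixed_seed_reproduces_null(self):
        y = ["posterior", "middle"] * 20
        X = pd.DataFrame({"x": np.random.default_rng(5).normal(0, 1, 40)})
        n1 = shuffle_chance(X, y, {"x": "continuous"}, iters=10,
                            rng=np.random.default_rng(7))
        n2 = shuffle_chance(X, y, {"x": "continuous"}, iters=10,
                            rng=np.random.default_rng(7))
        assert np.array_equal(n1.values, n2.values)
        assert n1.lo <= n1.mean <= n1.hi


class TestMouseChoicePrediction:
    def test_full_perseveration_is_perfectly_predictable(self):
        cfg = SimConfig(n_trials=120)
        pol = BehaviorPolicy(p_perseverate=1.0, sensory_noise=0.0)
        sess = generate_session(cfg, pol, np.random.default_rng(0),
                                with_frames=False)
        df = sess.trials.iloc[1:].reset_index(drop=True)
        prev = sess.trials["choice"].shift(1).iloc[1:].reset_index(drop=True)
        X = pd.DataFrame({"prev": prev})
        cv = predict_mouse_choice(X, df["choice"].to_numpy(dtype=object),
                                  {"prev": "categorical"},
                                  rng=np.random.default_rng(1))
        assert classifier_performance(
            cv.predicted, df["choice"].to_numpy(dtype=object)) == 1.0

    def test_iid_choices_predicted_at_null_agreement_rate(self):
        # uniform i.i.d. choices: expected accuracy Σ p_c² = 1/3
        rng = np.random.default_rng(2)
        choices = rng.choice(["posterior", "middle", "anterior"], 600)
        X = pd.DataFrame({"prev": np.roll(choices, 1)})
        cv = predict_mouse_choice(X[1:], choices[1:], {"prev": "categorical"},
                                  rng=rng)
        acc = classifier_performance(cv.predicted, choices[1:])
        assert abs(acc - 1 / 3) < 0.06

    def test_sensory_prediction_equals_location_prediction_for_ideal_mouse(self):
        cfg = SimConfig(n_trials=150)
        pol = BehaviorPolicy(p_perseverate=0.0, sensory_noise=0.0)
        sess = generate_session(cfg, pol, np.random.default_rng(3),
                                with_frames=False)
        y_loc = sess.trials["pole_location"].to_numpy(dtype=object)
        y_choice = sess.trials["choice"].to_numpy(dtype=object)
        X = pd.DataFrame({"t": sess.trials["true_touch"]})
        cv_loc = crossval_predict(X, y_loc, {"t": "categorical"},
                                  rng=np.random.default_rng(4))
        cv_ch = predict_mouse_choice(X, y_choice, {"t": "categorical"},
                                     rng=np.random.default_rng(4))
        assert classifier_performance(cv_loc.predicted, y_loc) == \
            classifier_performance(cv_ch.predicted, y_choice)


class TestParameterRecovery:
    def test_gaussian_fit_recovers_generative_parameters(self):
        rng = np.random.default_rng(0)
        mus = {"posterior": -1.0, "middle": 0.5, "anterior": 2.0}
        sd = 0.8
        n = 400
        y, x = [], []
        for cls, mu in mus.items():
            y += [cls] * n
            x.append(rng.normal(mu, sd, n))
        fit = fit_map_classifier(pd.DataFrame({"x": np.concatenate(x)}), y,
                                 {"x": "continuous"})
        g = fit.conditionals["x"]
        for cls, mu in mus.items():
            k = fit.classes.index(cls)
            assert abs(g["mean"][k] - mu) < 3 * sd / np.sqrt(n)
            assert abs(g["sd"][k] - sd) < 3 * sd / np.sqrt(2 * n)
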