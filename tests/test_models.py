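"""Feature transforms, elastic-net volume model, operating points, classifier."""

import numpy as np
import pandas as pd
import pytest

from xenoplasma.models import (
    MAX_SPEC_AT_FULL_SENS,
    YOUDEN,
    FeatureTransform,
    evaluate_classifier,
    evaluate_r2,
    impute_zero_volumes,
    make_design,
    predict_volume,
    scan_operating_point,
    split_holdout,
    train_elastic_net,
    train_type_classifier,
)


def frame(values, columns=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return pd.DataFrame(values, columns=columns
                        or [f"a{j}" for j in range(values.shape[1])])


class TestMakeDesign:
    def test_two_point_column_standardizes_to_pm_rsqrt2(self):
        x, _ = make_design(frame([[100.0], [1000.0]]), ["a0"])
        assert x["a0"].to_numpy() == pytest.approx(
            [-1 / np.sqrt(2), 1 / np.sqrt(2)], rel=1e-12)

    def test_stored_transform_reproduces_training_table(self):
        raw = frame(np.random.default_rng(0).lognormal(3, 1, (10, 4)))
        x, tf = make_design(raw, raw.columns)
        x2, _ = make_design(raw, raw.columns, tf)
        pd.testing.assert_frame_equal(x, x2)

    def test_test_data_uses_training_parameters_only(self):
        train = frame([[100.0], [1000.0]])
        test = frame([[10000.0]])
        _, tf = make_design(train, ["a0"])
        x_test, _ = make_design(test, ["a0"], tf)
        # (log10(1e4) - 2.5) / sd({2,3}) = 1.5 / sqrt(0.5)
        assert x_test.iloc[0, 0] == pytest.approx(1.5 / np.sqrt(0.5),
                                                  rel=1e-9)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            make_design(frame([[5.0, 1.0], [5.0, 2.0]]), ["a0", "a1"])

    def test_missing_marker_listed(self):
        with pytest.raises(KeyError, match="zz"):
            make_design(frame([[1.0], [2.0]]), ["zz"])


def toy_regression(n=40, p=6, informative=2, seed=0, noise=0.0,
                   intercept=20.0):
    """Linear toy on the cube-root scale with strictly positive response."""
    rng = np.random.default_rng(seed)
    x = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"a{j}" for j in range(p)])
    beta = np.zeros(p)
    beta[:informative] = [(2.0, -1.0)[k % 2] / (1 + k // 2)
                          for k in range(informative)]
    y_cbrt = x.to_numpy() @ beta + intercept + rng.normal(0, noise, n)
    assert (y_cbrt > 0).all()
    animals = np.repeat(np.arange(n // 4), 4)[:n]
    return x, y_cbrt, animals


class TestElasticNet:
    def test_lambda_zero_matches_least_squares_closed_form(self):
        x, y_cbrt, animals = toy_regression(noise=0.05)
        volumes = y_cbrt ** 3
        pred = train_elastic_net(x, volumes, animals, mixing_grid=[0.5],
                                 n_lambda=1, include_ols=True, seed=0)
        # closed-form normal equations on the cube-root response
        y = np.cbrt(volumes)
        xc = np.column_stack([np.ones(len(x)), x.to_numpy()])
        beta = np.linalg.lstsq(xc, y, rcond=None)[0]
        best = pred.cv_results.loc[pred.cv_results["cv_mse"].idxmin()]
        if best["lambda"] == 0:  # OLS won the grid; coefficients must match
            assert pred.coef.to_numpy() == pytest.approx(beta[1:], abs=1e-6)
            assert pred.intercept == pytest.approx(beta[0], abs=1e-6)
        else:  # refit the OLS point directly
            from xenoplasma.models import _fit_enet
            coef, icpt = _fit_enet(x.to_numpy(), y, 0.5, 0.0, 0)
            assert coef == pytest.approx(beta[1:], abs=1e-10)
            assert icpt == pytest.approx(beta[0], abs=1e-10)

    def test_huge_lambda_shrinks_all_slopes(self):
        from xenoplasma.models import _fit_enet

        x, y_cbrt, _ = toy_regression(noise=0.1)
        y = y_cbrt
        coef, icpt = _fit_enet(x.to_numpy(), y, 0.5, 1e6, 0)
        assert np.all(coef == 0)
        assert icpt == pytest.approx(y.mean(), rel=1e-9)

    def test_nonzero_count_monotone_in_lambda(self):
        from xenoplasma.models import _fit_enet, _lambda_max

        x, y_cbrt, _ = toy_regression(n=60, p=10, informative=3, noise=0.2)
        lam_max = _lambda_max(x.to_numpy(), y_cbrt, 1.0)
        counts = []
        for lam in np.geomspace(lam_max * 1e-4, lam_max * 1.1, 12):
            coef, _ = _fit_enet(x.to_numpy(), y_cbrt, 1.0, lam, 0)
            counts.append(int(np.sum(coef != 0)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_planted_support_recovered_across_seeds(self):
        """5 informative + 95 null features: the selected panel contains
        the informative set and stays small, across seeds."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n, p = 120, 100
            x = pd.DataFrame(rng.normal(size=(n, p)),
                             columns=[f"a{j}" for j in range(p)])
            beta = np.zeros(p)
            beta[:5] = [2.0, -1.5, 1.0, 0.8, -0.6]
            y = x.to_numpy() @ beta + 20.0 + rng.normal(0, 0.1, n)
            assert (y > 0).all()
            volumes = y ** 3
            animals = np.repeat(np.arange(30), 4)
            pred = train_elastic_net(x, volumes, animals, seed=seed)
            panel = set(pred.panel)
            assert {"a0", "a1", "a2", "a3", "a4"} <= panel
            assert len(panel) <= 15

    def test_noiseless_linear_toy_predicts_exactly(self):
        x, y_cbrt, animals = toy_regression(noise=0.0)
        volumes = y_cbrt ** 3
        pred = train_elastic_net(x, volumes, animals, mixing_grid=[0.5],
                                 n_lambda=3, include_ols=True, seed=0)
        out = predict_volume(pred, x)
        assert out == pytest.approx(volumes, rel=1e-6)


class TestPredictAndR2:
    def predictor(self, coef, intercept):
        from xenoplasma.models import VolumePredictor

        return VolumePredictor(markers=["a0"],
                               coef=pd.Series(coef, index=["a0"]),
                               intercept=intercept, mixing=0.5, strength=0.1,
                               transform=None)

    def test_positive_score_cubes(self):
        pred = self.predictor([0.0], 2.0)
        assert predict_volume(pred, frame([[1.0]]))[0] == pytest.approx(8.0)

    def test_negative_score_clamps_to_zero(self):
        pred = self.predictor([0.0], -0.5)
        assert predict_volume(pred, frame([[1.0]]))[0] == 0.0

    def test_perfect_predictions_r2_one(self):
        assert evaluate_r2([1, 8, 27], [1, 8, 27]) == pytest.approx(1.0)

    def test_mean_prediction_r2_zero(self):
        actual = np.array([1.0, 8.0, 27.0])
        mean_cbrt = np.cbrt(actual).mean() ** 3
        assert evaluate_r2(actual, [mean_cbrt] * 3) == pytest.approx(0.0)

    def test_cube_root_scale_hand_value(self):
        # cube roots {1,2,3} vs {1,2,4}: 1 - 1/2 = 0.5
        assert evaluate_r2([1, 8, 27], [1, 8, 64]) == pytest.approx(0.5)


class TestOperatingPoint:
    def test_separable_toy_reaches_perfect_point(self):
        pred = [0.1, 0.2, 0.3, 5.0, 10.0]
        labels = [False, False, False, True, True]
        points, sel = scan_operating_point(pred, labels)
        assert sel.threshold == pytest.approx(0.3)
        assert sel.sensitivity == 1.0 and sel.specificity == 1.0

    def test_one_false_positive_gives_15_16_specificity(self):
        # 16 non-tumor samples, one predicted above every tumor-compatible
        # threshold: best full-sensitivity point keeps 15/16 specificity
        non_tumor = [0.05 * i for i in range(1, 15)] + [0.75, 5.0]
        tumor = [1.0, 2.0, 40.0, 900.0]
        pred = non_tumor + tumor
        labels = [False] * 16 + [True] * 4
        _, sel = scan_operating_point(pred, labels)
        assert sel.sensitivity == 1.0
        assert sel.specificity == pytest.approx(15 / 16)
        assert sel.threshold == pytest.approx(0.75)

    def test_adversarial_order_still_returns_full_curve(self):
        pred = [1.0, 2.0, 0.1, 0.2]  # all tumor below all non-tumor
        labels = [False, False, True, True]
        points, sel = scan_operating_point(pred, labels)
        assert len(points) == 4
        assert sel is not None  # falls back to Youden

    def test_youden_rule(self):
        pred = [0.1, 0.9, 1.0, 2.0]
        labels = [False, True, True, True]
        _, sel = scan_operating_point(pred, labels, rule=YOUDEN)
        assert sel.sensitivity + sel.specificity == pytest.approx(2.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            scan_operating_point([1.0, 2.0], [True, True])


class TestImputeZeroVolumes:
    def samples(self):
        return pd.DataFrame({
            "Group": ["H1650", "H1975", "control"],
            "TumorVolume_mm3": [100.0, 200.0, 0.0],
        }, index=["s1", "s2", "s3"])

    def test_other_line_imputed_to_zero(self):
        vol = impute_zero_volumes(self.samples(), "H1650",
                                  ["H1650", "H1975"])
        assert vol["s2"] == 0.0

    def test_target_line_unchanged_and_control_zero(self):
        vol = impute_zero_volumes(self.samples(), "H1650",
                                  ["H1650", "H1975"])
        assert vol["s1"] == 100.0
        assert vol["s3"] == 0.0

    def test_unknown_line_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            impute_zero_volumes(self.samples(), "HT-29", ["H1650", "H1975"])


class TestSplitHoldout:
    def test_animals_not_split_across_sides(self):
        samples = pd.DataFrame({
            "Group": np.repeat(["g1", "g2"], 20),
            "AnimalId": np.repeat([f"m{i}" for i in range(10)], 4),
        }, index=[f"s{i}" for i in range(40)])
        train, test = split_holdout(samples, 0.25, seed=0)
        train_animals = set(samples.loc[train, "AnimalId"])
        test_animals = set(samples.loc[test, "AnimalId"])
        assert not (train_animals & test_animals)
        assert len(test) + len(train) == 40

    def test_fraction_approximately_respected(self):
        samples = pd.DataFrame({
            "Group": "g1",
            "AnimalId": np.repeat([f"m{i}" for i in range(98)], 4),
        }, index=[f"s{i}" for i in range(392)])
        _, test = split_holdout(samples, 107 / 392, seed=1)
        assert abs(len(test) / 392 - 0.27) < 0.02


class TestTypeClassifier:
    def separable(self, seed=0):
        rng = np.random.default_rng(seed)
        centers = {"A": (4, 0), "B": (0, 4), "C": (-4, -4)}
        rows, labels, animals = [], [], []
        for k, (cls, c) in enumerate(centers.items()):
            for i in range(24):
                rows.append(rng.normal(c, 0.3))
                labels.append(cls)
                animals.append(f"{cls}{i // 4}")
        x = pd.DataFrame(rows, columns=["f1", "f2"])
        return x, np.array(labels), np.array(animals)

    def test_separable_classes_classified_perfectly(self):
        x, y, animals = self.separable()
        clf = train_type_classifier(x, y, animals, mixing_grid=(0.5,),
                                    c_grid=(1.0,), seed=0)
        evaluate_classifier(clf, x, y)
        assert clf.accuracy == 1.0
        assert all(aucv == 1.0 for _, _, aucv in clf.roc.values())

    def test_probabilities_sum_to_one(self):
        x, y, animals = self.separable()
        clf = train_type_classifier(x, y, animals, mixing_grid=(0.5,),
                                    c_grid=(1.0,), seed=0)
        proba = clf.predict_proba(x)
        assert proba.sum(axis=1) == pytest.approx(np.ones(len(x)), abs=1e-9)

    def test_shuffled_labels_near_chance(self):
        accs = []
        for seed in range(5):
            x, y, animals = self.separable(seed)
            rng = np.random.default_rng(seed + 100)
            y_perm = rng.permutation(y)
            # animals grouped by shuffled labels are meaningless; use sample ids
            clf = train_type_classifier(x, y_perm, np.arange(len(x)),
                                        mixing_grid=(0.5,), c_grid=(1.0,),
                                        folds=3, seed=seed)
            holdout_x, _, _ = self.separable(seed + 50)
            y_h = rng.permutation(y)
            evaluate_classifier(clf, holdout_x, y_h)
            accs.append(clf.accuracy)
        # 3 classes: chance = 1/3; binomial 3-sigma band over 5x72 trials
        assert abs(np.mean(accs) - 1 / 3) < 3 * np.sqrt((1/3) * (2/3) / 360)

    def test_missing_class_in_fold_rejected(self):
        x, y, _ = self.separable()
        animals = np.where(y == "A", "onlyA", "rest")  # A isolated in a fold
        with pytest.raises(ValueError, match="absent"):
            train_type_classifier(x, y, animals, folds=2)
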