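import numpy as np
import pandas as pd
import pytest

from plasmadrift import (
    RdCvConfig,
    deserialize_model,
    permutation_test,
    rdcv_fit,
    rdcv_predict,
    serialize_model,
)
from plasmadrift.handling_predict import PredictError, _elimination_counts

FAST = dict(n_rep=1, n_outer=3, n_inner=2, var_ratio=0.5, n_trees=50)


def gaussian_classes(n_per_class=20, p=200, n_informative=5, sep=6.0, seed=0):
    """Two Gaussian clouds separated by `sep` sd in a few features."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (2 * n_per_class, p))
    X[n_per_class:, :n_informative] += sep
    y = np.array(["lo"] * n_per_class + ["hi"] * n_per_class)
    cols = [f"f{i}" for i in range(p)]
    return pd.DataFrame(X, columns=cols), y


def latent_regression_data(n=80, p=200, n_informative=5, noise=0.1, seed=0):
    """Outcome driven by a latent factor observed through 5 correlated
    features (the structure drift-feature clusters have)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, p))
    latent = rng.normal(0, 1, n)
    X[:, :n_informative] = latent[:, None] + rng.normal(0, 0.3, (n, n_informative))
    y = latent + rng.normal(0, noise, n)
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(p)]), y


class TestRdcvFit:
    def test_separable_classes_perfectly_classified(self):
        X, y = gaussian_classes(seed=1)
        cfg = RdCvConfig(**FAST, fitness="misclassification", seed=5)
        model = rdcv_fit(X, y, cfg)
        assert model.performance["n_misclassified"] == 0
        assert model.task == "classification"

    def test_linear_signal_regression_reaches_high_q2(self):
        X, y = latent_regression_data(seed=2)
        cfg = RdCvConfig(n_rep=1, n_outer=4, n_inner=3, var_ratio=0.5,
                         n_trees=100, fitness="rmsep", seed=6)
        model = rdcv_fit(X, y, cfg)
        assert model.performance["q2"] >= 0.8

    def test_q2_does_not_exceed_r2(self):
        X, y = latent_regression_data(seed=3)
        cfg = RdCvConfig(**FAST, fitness="rmsep", seed=7)
        model = rdcv_fit(X, y, cfg)
        assert model.performance["q2"] <= model.performance["r2"]

    def test_degenerate_outcomes_rejected(self):
        X, _ = gaussian_classes(n_per_class=10, p=20)
        with pytest.raises(PredictError, match="single class"):
            rdcv_fit(X, ["a"] * 20, RdCvConfig(**FAST, fitness="misclassification"))
        with pytest.raises(PredictError, match="zero-variance"):
            rdcv_fit(X, np.ones(20), RdCvConfig(**FAST, fitness="rmsep"))

    def test_class_smaller_than_outer_folds_rejected(self):
        X, _ = gaussian_classes(n_per_class=10, p=20)
        y = np.array(["a"] * 18 + ["b"] * 2)
        with pytest.raises(PredictError, match="outer folds"):
            rdcv_fit(X, y, RdCvConfig(**FAST, fitness="misclassification"))

    def test_deterministic_under_seed(self):
        X, y = gaussian_classes(n_per_class=10, p=30, seed=4)
        cfg = RdCvConfig(**FAST, fitness="misclassification", seed=11)
        a = rdcv_fit(X, y, cfg)
        b = rdcv_fit(X, y, cfg)
        assert a.selected_variables == b.selected_variables
        pd.testing.assert_frame_equal(a.per_sample_prediction, b.per_sample_prediction)

    def test_selected_variables_contain_informative_features(self):
        X, y = gaussian_classes(seed=1)
        cfg = RdCvConfig(**FAST, fitness="misclassification", seed=5)
        model = rdcv_fit(X, y, cfg)
        informative = {f"f{i}" for i in range(5)}
        # the minimal consensus set must consist purely of informative features
        assert set(model.selected_variables["min"]) <= informative

    def test_monotone_accuracy_in_class_separation(self):
        accs = []
        for sep in (0.5, 2.0, 6.0):
            X, y = gaussian_classes(n_per_class=15, p=60, sep=sep, seed=8)
            cfg = RdCvConfig(**FAST, fitness="misclassification", seed=9)
            accs.append(rdcv_fit(X, y, cfg).performance["accuracy"])
        assert accs[0] <= accs[1] + 0.1 and accs[1] <= accs[2] + 0.1
        assert accs[2] >= 0.95

    def test_no_leakage_under_permuted_outcome(self):
        X, y = latent_regression_data(n=60, p=80, seed=10)
        q2s = []
        for seed in (0, 1):
            rng = np.random.default_rng(seed)
            cfg = RdCvConfig(**FAST, fitness="rmsep", seed=20 + seed)
            q2s.append(rdcv_fit(X, rng.permutation(y), cfg).performance["q2"])
        assert np.mean(q2s) <= 0.1

    def test_group_aware_folds_keep_subjects_together(self):
        # leakage check: with strong subject effects and grouped folds the
        # model cannot exploit subject identity
        rng = np.random.default_rng(12)
        n_subj, per_subj, p = 12, 4, 30
        subj_effect = rng.normal(0, 2, (n_subj, p))
        X = np.repeat(subj_effect, per_subj, axis=0) + rng.normal(
            0, 0.1, (n_subj * per_subj, p)
        )
        y = rng.permutation(np.repeat([0.0, 10.0, 20.0, 30.0], 12))
        groups = np.repeat([f"s{i}" for i in range(n_subj)], per_subj)
        cfg = RdCvConfig(**FAST, fitness="rmsep", seed=13)
        model = rdcv_fit(pd.DataFrame(X), y, cfg, groups=groups)
        assert model.performance["q2"] <= 0.1


@pytest.fixture(scope="module")
def class_model():
    X, y = gaussian_classes(seed=1)
    cfg = RdCvConfig(**FAST, fitness="misclassification", seed=5)
    return rdcv_fit(X, y, cfg)


class TestRdcvPredict:

    def test_generalizes_to_fresh_draw(self, class_model):
        Xnew, ynew = gaussian_classes(seed=99)
        pred = rdcv_predict(class_model, Xnew)
        acc = (pred == ynew).mean()
        assert acc >= class_model.performance["accuracy"] - 0.05

    def test_single_sample(self, class_model):
        Xnew, _ = gaussian_classes(seed=99)
        pred = rdcv_predict(class_model, Xnew.iloc[:1])
        assert len(pred) == 1

    def test_constant_table_warns_and_predicts(self, class_model):
        Xnew, _ = gaussian_classes(seed=99)
        const = Xnew.iloc[:4] * 0.0
        with pytest.warns(UserWarning, match="constant"):
            pred = rdcv_predict(class_model, const)
        assert set(pred) <= {"lo", "hi"}

    def test_missing_features_beyond_tolerance_rejected(self, class_model):
        Xnew, _ = gaussian_classes(seed=99)
        cols = class_model.selected_variables["mid"]
        dropped = Xnew.drop(columns=cols[: max(2, len(cols) // 2)])
        with pytest.raises(PredictError, match="missing"):
            rdcv_predict(class_model, dropped)

    def test_serialization_round_trip_identical_predictions(self, class_model, tmp_path):
        path = tmp_path / "model.json"
        serialize_model(class_model, path)
        back = deserialize_model(path)
        Xnew, _ = gaussian_classes(seed=77)
        np.testing.assert_array_equal(
            rdcv_predict(class_model, Xnew), rdcv_predict(back, Xnew)
        )
        pd.testing.assert_frame_equal(
            class_model.per_sample_prediction, back.per_sample_prediction
        )


class TestPermutationTest:
    def test_signal_beats_all_nulls_gives_minimal_p(self):
        X, y = gaussian_classes(n_per_class=12, p=40, seed=14)
        cfg = RdCvConfig(**FAST, fitness="misclassification", seed=15)
        res = permutation_test(X, y, cfg, n_perm=6, perm_n_rep=1)
        assert (res.null_values > res.observed).all()
        assert res.p_empirical == pytest.approx(1 / 7)
        assert res.p_parametric < 0.05

    def test_too_few_permutations_rejected(self):
        X, y = gaussian_classes(n_per_class=6, p=10)
        with pytest.raises(PredictError, match="n_perm"):
            permutation_test(X, y, RdCvConfig(**FAST), n_perm=1)


def test_elimination_schedule_strictly_decreasing():
    for p, ratio in [(478, 0.75), (478, 0.5), (10, 0.9), (3, 0.5)]:
        counts = _elimination_counts(p, ratio)
        assert counts[0] == p and counts[-1] == 2
        assert all(a > b for a, b in zip(counts, counts[1:]))
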