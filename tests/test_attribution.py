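"""Shapley axioms, the enumeration oracle and the exact tree fast path."""

import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier

from ecgxai.attribution import (AttributionMatrix, BackgroundSpec,
                                compute_attributions, exact_shapley,
                                linear_interventional_shap, permutation_shap)
from ecgxai._treeshap import forest_interventional_shap
from ecgxai.classifiers import ModelSpec, TrainedModel


def small_forest(p=6, n=200, seed=0, trees=25):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = (X[:, 0] + 0.7 * X[:, 1] - 0.5 * X[:, 2] * X[:, 3]
         + 0.3 * rng.standard_normal(n)) > 0
    rf = RandomForestClassifier(n_estimators=trees, random_state=seed).fit(X, y)
    pos = list(rf.classes_).index(True)
    return rf, (lambda M: rf.predict_proba(M)[:, pos]), X, pos


class TestExactOracle:
    def test_efficiency_axiom_holds_exactly(self):
        rf, f, X, _ = small_forest()
        bg = X[:12]
        base = f(bg).mean()
        for i in range(4):
            phi = exact_shapley(f, X[i], bg)
            assert abs(base + phi.sum() - f(X[i:i + 1])[0]) < 1e-10

    def test_symmetry_axiom_for_duplicated_features(self):
        # f depends symmetrically on features 0 and 1
        f = lambda M: M[:, 0] + M[:, 1] + 0.5 * M[:, 2]
        rng = np.random.default_rng(2)
        bg = rng.standard_normal((16, 3))
        x = np.array([1.3, 1.3, -0.4])  # identical values on the symmetric pair
        bg[:, 1] = bg[:, 0]             # background symmetric between them too
        phi = exact_shapley(f, x, bg)
        assert abs(phi[0] - phi[1]) < 1e-12

    def test_dummy_feature_gets_exactly_zero(self):
        f = lambda M: np.sin(M[:, 0]) + M[:, 2] ** 2
        rng = np.random.default_rng(3)
        phi = exact_shapley(f, rng.standard_normal(4), rng.standard_normal((10, 4)))
        assert phi[1] == 0.0
        assert phi[3] == 0.0

    def test_constant_model_attributes_nothing(self):
        f = lambda M: np.full(len(M), 0.37)
        phi = exact_shapley(f, np.zeros(5), np.zeros((8, 5)))
        np.testing.assert_array_equal(phi, np.zeros(5))

    def test_combinatorial_guard_refuses_large_p(self):
        with pytest.raises(ValueError, match="refused"):
            exact_shapley(lambda M: M.sum(1), np.zeros(13), np.zeros((4, 13)))


class TestLinearClosedForm:
    def test_oracle_reproduces_linear_closed_form(self):
        rng = np.random.default_rng(4)
        w = rng.standard_normal(7)
        f = lambda M: M @ w + 0.2
        x = rng.standard_normal(7)
        bg = rng.standard_normal((30, 7))
        expected = linear_interventional_shap(w, x, bg)
        np.testing.assert_allclose(exact_shapley(f, x, bg), expected, atol=1e-10)

    def test_permutation_sampler_is_exact_for_linear_models(self):
        rng = np.random.default_rng(5)
        w = rng.standard_normal(15)
        f = lambda M: M @ w
        X = rng.standard_normal((3, 15))
        bg = rng.standard_normal((20, 15))
        got = permutation_shap(f, X, bg, n_permutations=4, seed=0)
        for i in range(3):
            np.testing.assert_allclose(
                got[i], linear_interventional_shap(w, X[i], bg), atol=1e-10)


class TestTreeFastPath:
    def test_tree_path_matches_enumeration_oracle_to_1e8(self):
        rf, f, X, pos = small_forest(p=8, trees=20, seed=1)
        bg = X[:16]
        fast = forest_interventional_shap(rf, X[:6], bg, pos)
        for i in range(6):
            oracle = exact_shapley(f, X[i], bg)
            assert np.abs(fast[i] - oracle).max() < 1e-8

    def test_efficiency_holds_rowwise_within_1e6(self):
        rf, f, X, pos = small_forest(p=10, trees=40, seed=2)
        bg = X[:32]
        phi = forest_interventional_shap(rf, X[:20], bg, pos)
        base = f(bg).mean()
        np.testing.assert_allclose(base + phi.sum(axis=1), f(X[:20]), atol=1e-6)

    def test_feature_never_split_on_gets_zero(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((150, 5))
        X[:, 4] = 0.0                   # constant column: never split on
        y = X[:, 0] > 0
        rf = RandomForestClassifier(n_estimators=10, max_depth=2,
                                    random_state=0).fit(X, y)
        used = set()
        for est in rf.estimators_:
            used |= set(est.tree_.feature[est.tree_.feature >= 0])
        unused = [j for j in range(5) if j not in used]
        assert unused, "toy forest unexpectedly used every feature"
        pos = list(rf.classes_).index(True)
        phi = forest_interventional_shap(rf, X[:10], X[:20], pos)
        np.testing.assert_array_equal(phi[:, unused], 0.0)


class TestComputeAttributions:
    def test_high_level_entry_checks_efficiency_and_ids(self):
        rf, f, X, pos = small_forest(p=6)
        model = TrainedModel(ModelSpec(seed=0), rf, [f"f{j}" for j in range(6)])
        attr = compute_attributions(model, X[:9], BackgroundSpec(size=16, seed=0),
                                    X, record_ids=[f"r{i}" for i in range(9)])
        assert attr.values.shape == (9, 6)
        res = attr.efficiency_residuals(model.predict_proba(X[:9]))
        assert np.abs(res).max() < 1e-6

    def test_background_must_be_nonempty(self):
        with pytest.raises(ValueError):
            BackgroundSpec(size=0)
        rf, _, X, _ = small_forest(p=6)
        model = TrainedModel(ModelSpec(seed=0), rf, [f"f{j}" for j in range(6)])
        with pytest.raises(ValueError, match="empty"):
            compute_attributions(model, X[:2], BackgroundSpec(size=4),
                                 np.empty((0, 6)))

    def test_matrix_round_trips_through_csv(self, tmp_path):
        rng = np.random.default_rng(7)
        attr = AttributionMatrix(rng.standard_normal((4, 3)), 0.21,
                                 ["a", "b", "c", "d"], ["x", "y", "z"])
        attr.to_csv(tmp_path / "m.csv", sidecar=tmp_path / "m.json")
        back = AttributionMatrix.from_csv(tmp_path / "m.csv", tmp_path / "m.json")
        np.testing.assert_array_equal(back.values, attr.values)
        assert back.base_value == attr.base_value
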