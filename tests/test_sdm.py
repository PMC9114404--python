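import numpy as np
import pandas as pd
import pytest

from benthoscape import sdm
from benthoscape.grids import Grid, GridStack
from benthoscape.survey import PresenceAbsenceMatrix


@pytest.fixture(scope="module")
def planted_env():
    """Env stack whose depth field carries a clean planted signal."""
    rng = np.random.default_rng(0)
    n = 30
    depth = Grid(rng.uniform(2000, 4400, (n, n)), 100.0, 0.0, n * 100.0)
    noise = Grid(rng.normal(size=(n, n)), 100.0, 0.0, n * 100.0)
    return GridStack({"depth": depth, "noise": noise})


@pytest.fixture(scope="module")
def planted_training(planted_env):
    """500 images; presence iff depth < 3000 (fully separable)."""
    rng = np.random.default_rng(1)
    n = 500
    xs = rng.uniform(0, 3000, n)
    ys = rng.uniform(0, 3000, n)
    images = pd.DataFrame({"image_id": [f"I{i}" for i in range(n)],
                           "x": xs, "y": ys})
    predictors, dropped = sdm.build_predictor_table(images, planted_env)
    presence = (predictors["depth"] < 3000).astype(int)
    return images, predictors, presence


class TestPredictorTable:
    def test_values_are_cell_lookups(self, planted_env):
        images = pd.DataFrame({"image_id": ["a"], "x": [150.0], "y": [2850.0]})
        table, dropped = sdm.build_predictor_table(images, planted_env)
        assert table.loc[0, "depth"] == planted_env["depth"].values[1, 1]
        assert not dropped

    def test_same_cell_same_row(self, planted_env):
        images = pd.DataFrame({"image_id": ["a", "b"],
                               "x": [150.0, 160.0], "y": [2850.0, 2860.0]})
        table, _ = sdm.build_predictor_table(images, planted_env)
        assert table.iloc[0].equals(table.iloc[1])

    def test_images_on_nodata_dropped_and_reported(self, planted_env):
        images = pd.DataFrame({"image_id": ["a", "b"],
                               "x": [150.0, -999.0], "y": [2850.0, 2850.0]})
        table, dropped = sdm.build_predictor_table(images, planted_env)
        assert dropped == ["b"]
        assert len(table) == 1


class TestFitMorphotypeModel:
    def test_separable_signal_has_low_oob_error(self, planted_training):
        _, predictors, presence = planted_training
        model = sdm.fit_morphotype_model(presence, predictors,
                                         sdm.RFConfig(seed=0), "sep")
        assert model.oob_error < 0.05

    def test_pure_noise_has_chance_level_oob_error(self, planted_training):
        _, predictors, _ = planted_training
        rng = np.random.default_rng(2)
        presence = rng.integers(0, 2, len(predictors))
        model = sdm.fit_morphotype_model(presence, predictors,
                                         sdm.RFConfig(seed=0), "null")
        assert model.oob_error == pytest.approx(0.5, abs=0.07)

    def test_single_class_response_rejected(self, planted_training):
        _, predictors, _ = planted_training
        with pytest.raises(sdm.DegenerateResponseError):
            sdm.fit_morphotype_model(np.ones(len(predictors)), predictors,
                                     morphotype_id="allpresent")

    def test_training_cells_classified_correctly(self, planted_training,
                                                 planted_env):
        _, predictors, presence = planted_training
        model = sdm.fit_morphotype_model(presence, predictors,
                                         sdm.RFConfig(seed=0), "sep")
        proba = model.forest.predict_proba(predictors.to_numpy())[:, 1]
        correct = (proba > 0.5) == presence.astype(bool)
        assert correct.mean() >= 0.95


class TestPredictProbability:
    def test_single_tree_votes_are_binary(self, planted_training, planted_env):
        _, predictors, presence = planted_training
        model = sdm.fit_morphotype_model(
            presence, predictors, sdm.RFConfig(n_trees=1, seed=0), "one")
        grid = sdm.predict_probability(model, planted_env)
        vals = grid.values[grid.valid_mask]
        assert set(np.unique(vals)) <= {0.0, 1.0}

    def test_probabilities_bounded_and_signal_recovered(self, planted_training,
                                                        planted_env):
        _, predictors, presence = planted_training
        model = sdm.fit_morphotype_model(presence, predictors,
                                         sdm.RFConfig(seed=0), "sep")
        grid = sdm.predict_probability(model, planted_env)
        vals = grid.values[grid.valid_mask]
        assert vals.min() >= 0.0 and vals.max() <= 1.0
        depth = planted_env["depth"].values[grid.valid_mask]
        assert vals[depth < 2800].mean() > 0.9
        assert vals[depth > 3200].mean() < 0.1

    def test_missing_predictor_layer_is_key_error(self, planted_training):
        _, predictors, presence = planted_training
        model = sdm.fit_morphotype_model(presence, predictors,
                                         sdm.RFConfig(seed=0), "sep")
        with pytest.raises(KeyError, match="noise"):
            sdm.predict_probability(
                model, GridStack({"depth": Grid(np.ones((3, 3)), 1.0)}))


class TestFitAll:
    def _matrix(self, predictors, columns):
        rng = np.random.default_rng(3)
        data = {}
        for name in columns:
            data[name] = (predictors["depth"].to_numpy()
                          < rng.uniform(2500, 3500)).astype(int)
        return PresenceAbsenceMatrix(pd.DataFrame(data))

    def test_one_layer_per_morphotype(self, planted_training, planted_env):
        _, predictors, _ = planted_training
        matrix = self._matrix(predictors, ["m1", "m2", "m3"])
        stack, failures = sdm.fit_all(matrix, predictors, planted_env,
                                      sdm.RFConfig(n_trees=20, seed=0))
        assert len(stack) == 3 and not failures
        assert set(stack.registry()["morphotype_id"]) == {"m1", "m2", "m3"}

    def test_empty_matrix_gives_empty_stack(self, planted_training, planted_env):
        _, predictors, _ = planted_training
        matrix = PresenceAbsenceMatrix(pd.DataFrame(index=predictors.index))
        stack, failures = sdm.fit_all(matrix, predictors, planted_env)
        assert len(stack) == 0

    def test_degenerate_columns_logged_not_fatal(self, planted_training,
                                                 planted_env):
        _, predictors, _ = planted_training
        matrix = self._matrix(predictors, ["ok"])
        matrix.values["bad"] = 1
        stack, failures = sdm.fit_all(matrix, predictors, planted_env,
                                      sdm.RFConfig(n_trees=20, seed=0))
        assert "bad" in failures and len(stack) == 1

    def test_column_order_does_not_change_results(self, planted_training,
                                                  planted_env):
        _, predictors, _ = planted_training
        matrix = self._matrix(predictors, ["m1", "m2"])
        reversed_matrix = PresenceAbsenceMatrix(matrix.values[["m2", "m1"]])
        s1, _ = sdm.fit_all(matrix, predictors, planted_env,
                            sdm.RFConfig(n_trees=20, seed=5))
        s2, _ = sdm.fit_all(reversed_matrix, predictors, planted_env,
                            sdm.RFConfig(n_trees=20, seed=5))
        np.testing.assert_array_equal(s1["m1"].values, s2["m1"].values)
        assert s1.models["m1"].oob_error == s2.models["m1"].oob_error


class TestInterpolatePoints:
    def test_linear_function_of_depth_recovered(self, planted_env):
        rng = np.random.default_rng(4)
        xs = rng.uniform(0, 3000, 100)
        ys = rng.uniform(0, 3000, 100)
        depth_at = planted_env["depth"].sample(xs, ys)
        points = pd.DataFrame({"x": xs, "y": ys,
                               "value": 0.01 * depth_at - 20.0})
        grid, oob_r2, excluded = sdm.interpolate_point_samples(
            points, planted_env, sdm.RFConfig(n_trees=100, seed=0))
        mask = grid.valid_mask
        truth = 0.01 * planted_env["depth"].values[mask] - 20.0
        assert np.corrcoef(grid.values[mask], truth)[0, 1] > 0.95
        assert not excluded

    def test_constant_value_predicts_constant(self, planted_env):
        rng = np.random.default_rng(5)
        points = pd.DataFrame({"x": rng.uniform(0, 3000, 20),
                               "y": rng.uniform(0, 3000, 20), "value": 3.5})
        grid, _, _ = sdm.interpolate_point_samples(
            points, planted_env, sdm.RFConfig(n_trees=20, seed=0))
        np.testing.assert_allclose(grid.values[grid.valid_mask], 3.5)

    def test_off_grid_points_excluded_and_minimum_enforced(self, planted_env):
        points = pd.DataFrame({"x": [-1.0] * 12, "y": [0.0] * 12,
                               "value": 1.0})
        with pytest.raises(ValueError, match=">= 10"):
            sdm.interpolate_point_samples(points, planted_env)
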