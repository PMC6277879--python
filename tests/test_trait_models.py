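import numpy as np
import pytest
from scipy import stats

from carrotmorph.imaging import PlantMask, segment_image
from carrotmorph.synthetic import SyntheticPlantSpec, generate_population, render_plant
from carrotmorph.trait_models import (PetioleLengthRegressor,
                                      PetioleWidthRegressor,
                                      PlsTraitRegressor, fit_length_model,
                                      fit_pls, load_model_json,
                                      petiole_count_feature,
                                      predict_petiole_number,
                                      save_model_json, skeleton_edt_samples,
                                      width_feature)


class TestWidthFeature:
    def test_bar_edt_approximates_half_width(self):
        grid = np.zeros((40, 120), dtype=np.uint8)
        grid[17:24, 10:110] = 1  # horizontal bar, width 7
        samples = skeleton_edt_samples(PlantMask(grid))
        core = samples[(samples > 0)]
        assert np.median(core) == pytest.approx(3.5, abs=0.75)

    def test_descriptor_sums_to_one(self):
        grid = np.zeros((40, 40), dtype=np.uint8)
        grid[10:20, 5:35] = 1
        feat = width_feature(PlantMask(grid))
        assert feat.descriptor.sum() == pytest.approx(1.0)
        assert (feat.descriptor >= 0).all()
        assert feat.n_skeleton_px > 0

    def test_petiole_width_mode_matches_ground_truth(self):
        w = 9.0
        spec = SyntheticPlantSpec(
            seed=0, height=400, width=400, divider_row=300, crown_col=200,
            root_length_px=60, root_max_width_px=30, taper_k=1.0,
            tip_bluntness=0.2,
            petioles=tuple((a, 180.0, w, 14.0) for a in (60, 80, 100, 120)),
        )
        img, _ = render_plant(spec)
        segments = segment_image(img)
        samples = skeleton_edt_samples(segments.shoot_mask)
        widths = np.round(2 * samples).astype(int)
        mode = np.bincount(widths).argmax()
        assert abs(mode - w) <= 1

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            width_feature(PlantMask(np.zeros((10, 10), dtype=np.uint8)))


class TestPlsRegressor:
    def test_exactly_linear_target_is_recovered(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 6))
        y = 3.0 * X[:, 2] + 10.0
        model = fit_pls(X, y, clamp_nonnegative=False)
        # selected CV error is negligible next to the target spread
        assert np.nanmin(model.cv_rmse_by_k_[:model.n_components_]) \
            <= 1e-3 * y.std()
        pred = model.predict(X)
        ss_res = np.sum((y - pred) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot >= 0.999

    def test_single_predictor_selects_one_component(self):
        rng = np.random.default_rng(20)
        X = rng.uniform(0, 10, size=(30, 1))
        model = fit_pls(X, 2.0 * X[:, 0] + 1.0, clamp_nonnegative=False)
        assert model.n_components_ == 1

    def test_permuted_targets_have_no_skill(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 8))
        y = rng.permutation(3.0 * X[:, 0] + rng.normal(size=50))
        model = fit_pls(X, y, clamp_nonnegative=False)
        best_rmse = np.nanmin(model.cv_rmse_by_k_)
        assert best_rmse == pytest.approx(y.std(), rel=0.3)

    def test_refit_is_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=30) * 0.1
        m1 = fit_pls(X, y)
        m2 = fit_pls(X, y)
        np.testing.assert_array_equal(m1.coef_, m2.coef_)
        assert m1.intercept_ == m2.intercept_
        assert m1.n_components_ == m2.n_components_

    def test_full_rank_pls_equals_ols(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=30)
        from sklearn.cross_decomposition import PLSRegression
        pls = PLSRegression(n_components=5).fit(X, y)
        Xd = np.column_stack([np.ones(30), X])
        beta = np.linalg.lstsq(Xd, y, rcond=None)[0]
        np.testing.assert_allclose(
            pls.predict(X).ravel(), Xd @ beta, rtol=1e-6, atol=1e-8)

    def test_constant_targets_give_constant_prediction(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 4))
        model = fit_pls(X, np.full(20, 7.5))
        np.testing.assert_allclose(model.predict(X), 7.5, atol=1e-8)

    def test_predictions_clamped_nonnegative(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 3))
        y = np.maximum(X[:, 0], 0)
        model = fit_pls(X, y)
        assert (model.predict(rng.normal(size=(50, 3)) - 5) >= 0).all()

    def test_feature_length_mismatch_rejected(self):
        rng = np.random.default_rng(6)
        model = fit_pls(rng.normal(size=(20, 4)), rng.normal(size=20))
        with pytest.raises(ValueError, match="feature length"):
            model.predict(rng.normal(size=(3, 7)))


class TestCountFeature:
    def test_ratio_arithmetic(self):
        grid = np.zeros((50, 50), dtype=np.uint8)
        grid[:40, :25] = 1  # area 1000
        assert petiole_count_feature(PlantMask(grid), 10.0) == 100.0

    def test_empty_shoot_gives_zero(self):
        empty = PlantMask(np.zeros((10, 10), dtype=np.uint8))
        assert petiole_count_feature(empty, 5.0) == 0.0

    def test_zero_width_rejected(self):
        grid = np.ones((5, 5), dtype=np.uint8)
        with pytest.raises(ValueError):
            petiole_count_feature(PlantMask(grid), 0.0)

    def test_ratio_tracks_count_at_fixed_width_and_length(self):
        images, truth = generate_population(
            50, seed=11,
            overrides={"petiole_count": (5, 15), "petiole_length": 200.0,
                       "petiole_width": 8.0})
        ratios = []
        for img in images:
            seg = segment_image(img)
            ratios.append(petiole_count_feature(seg.shoot_mask, 8.0))
        rho = stats.spearmanr(ratios, truth["petiole_count"]).statistic
        assert rho >= 0.9


class TestLengthModel:
    def test_uninformative_features_predict_mean(self):
        rng = np.random.default_rng(7)
        sbps = np.tile(np.linspace(5, 0, 60), (25, 1))
        y = rng.uniform(10, 30, size=25)
        model = fit_length_model(sbps, y, seed=0)
        pred = model.predict(sbps)
        assert np.allclose(pred, y.mean(), atol=0.25 * y.std())

    def test_same_seed_same_data_bit_identical(self):
        rng = np.random.default_rng(8)
        sbps = rng.uniform(size=(30, 40))
        y = sbps[:, :5].sum(axis=1) * 3
        m1 = fit_length_model(sbps, y, seed=3)
        m2 = fit_length_model(sbps, y, seed=3)
        np.testing.assert_array_equal(m1.predict(sbps), m2.predict(sbps))
        np.testing.assert_array_equal(m1.w1_, m2.w1_)

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError, match="20"):
            fit_length_model(rng.uniform(size=(10, 30)), rng.uniform(size=10))


class TestPersistence:
    def test_pls_round_trip(self, tmp_path):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(25, 6))
        y = X[:, 1] * 2 + 5
        model = fit_pls(X, y)
        path = tmp_path / "pls.json"
        save_model_json(model, path)
        loaded = load_model_json(path)
        np.testing.assert_array_equal(model.predict(X), loaded.predict(X))

    def test_width_model_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        samples = [rng.uniform(1, 6, size=rng.integers(50, 200))
                   for _ in range(15)]
        y = np.array([np.median(s) for s in samples])
        model = PetioleWidthRegressor(max_components=4).fit(samples, y)
        path = tmp_path / "width.json"
        save_model_json(model, path)
        loaded = load_model_json(path)
        np.testing.assert_array_equal(
            model.predict(samples), loaded.predict(samples))
        assert loaded.edt_cap_ == model.edt_cap_

    def test_length_model_round_trip(self, tmp_path):
        rng = np.random.default_rng(12)
        sbps = rng.uniform(size=(25, 40))
        y = sbps.sum(axis=1)
        model = PetioleLengthRegressor(seed=1).fit(sbps, y)
        path = tmp_path / "length.json"
        save_model_json(model, path)
        loaded = load_model_json(path)
        np.testing.assert_array_equal(model.predict(sbps), loaded.predict(sbps))


def test_predict_petiole_number_wrapper():
    rng = np.random.default_rng(13)
    X = rng.uniform(50, 150, size=(30, 1))
    y = X[:, 0] / 10
    model = PlsTraitRegressor(max_components=1).fit(X, y)
    value = predict_petiole_number(model, [100.0])
    assert value == pytest.approx(10.0, rel=0.05)
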