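"""Single-component PLS: closed form vs an independent loop-NIPALS oracle
and scikit-learn, plus map prediction, consensus averaging and ROI medians."""

import numpy as np
import pytest

from rpmap import (DegenerateModelError, Pls1Model, consensus_map,
                   extract_lesions, fit_pls1, generate_cohort, predict_map,
                   roi_prediction)
from rpmap.phantom import FEATURE_NAMES, DensityMap, FeatureVolume

from conftest import quiet_config
from oracles import pls1_nipals_loops


class TestFitPls1:
    def test_matches_loop_nipals_oracle_on_random_problems(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            X = rng.normal(size=(8, 6))
            y = X @ rng.normal(size=6)
            model = fit_pls1(X, y)
            Xnew = rng.normal(size=(5, 6))
            expected = pls1_nipals_loops(X.tolist(), y.tolist(), Xnew.tolist())
            np.testing.assert_allclose(model.predict(Xnew), expected,
                                       atol=1e-10)
            # training rows reproduced through the back-transformed betas
            np.testing.assert_allclose(
                model.predict(X),
                pls1_nipals_loops(X.tolist(), y.tolist(), X.tolist()),
                atol=1e-10)

    def test_weight_proportional_to_feature_target_covariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=50)
        model = fit_pls1(X, y)
        Xc = (X - X.mean(0)) / X.std(0, ddof=1)
        cov = Xc.T @ (y - y.mean())
        np.testing.assert_allclose(model.w, cov / np.linalg.norm(cov),
                                   atol=1e-10)
        assert np.linalg.norm(model.w) == pytest.approx(1.0, abs=1e-12)

    def test_matches_sklearn_single_component(self):
        from sklearn.cross_decomposition import PLSRegression
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 6))
        y = X @ rng.normal(size=6) + 0.3 * rng.normal(size=40)
        model = fit_pls1(X, y)
        sk = PLSRegression(n_components=1, scale=True).fit(X, y)
        Xnew = rng.normal(size=(15, 6))
        np.testing.assert_allclose(model.predict(Xnew),
                                   sk.predict(Xnew).ravel(), atol=1e-10)

    def test_constant_target_is_degenerate(self):
        X = np.random.default_rng(3).normal(size=(10, 6))
        with pytest.raises(DegenerateModelError):
            fit_pls1(X, np.full(10, 0.5))

    def test_uncorrelated_target_is_degenerate(self):
        # y varies but has exactly zero sample covariance with every column
        X = np.zeros((8, 6))
        X[:4, :] = 1.0
        X[4:, :] = -1.0
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        with pytest.raises((DegenerateModelError, ValueError)):
            fit_pls1(X, y)

    def test_zero_variance_feature_named_in_error(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 6))
        X[:, 2] = 7.0
        with pytest.raises(ValueError, match=FEATURE_NAMES[2]):
            fit_pls1(X, rng.normal(size=10))

    def test_needs_more_rows_than_features(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="training rows"):
            fit_pls1(rng.normal(size=(6, 6)), rng.normal(size=6))

    def test_single_informative_feature_approaches_ols(self):
        # X[:, 0] = y exactly, other columns pure noise: the standardized
        # weight concentrates on column 0 and the prediction approaches the
        # OLS-on-column-0 oracle (y itself) as n grows, since the noise
        # columns' spurious covariance with y scales like 1/sqrt(n)
        rng = np.random.default_rng(6)
        rmses = []
        for n in (250, 4000):
            y = rng.normal(size=n)
            X = rng.normal(size=(n, 6))
            X[:, 0] = y
            model = fit_pls1(X, y)
            rmses.append(np.sqrt(np.mean((model.predict(X) - y) ** 2)))
        assert rmses[1] < rmses[0] < 0.25
        assert rmses[1] < 0.08
        assert abs(model.w[0]) > 0.99  # weight mass on the informative feature

    def test_prediction_invariant_to_feature_rescaling(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=30)
        Xnew = rng.normal(size=(10, 6))
        base = fit_pls1(X, y).predict(Xnew)
        scale = np.array([3.0, 0.2, 1.0, 10.0, 1.0, 0.5])
        rescaled = fit_pls1(X * scale, y).predict(Xnew * scale)
        np.testing.assert_allclose(rescaled, base, atol=1e-8)

    def test_serialization_round_trip(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 6))
        model = fit_pls1(X, X @ rng.normal(size=6))
        clone = Pls1Model.from_dict(model.to_dict())
        np.testing.assert_allclose(clone.predict(X), model.predict(X),
                                   atol=1e-14)


class TestPredictMap:
    def _volume(self, shape=(30, 30)):
        rng = np.random.default_rng(9)
        mask = np.ones(shape, bool)
        return FeatureVolume(data=rng.normal(size=shape + (6,)),
                             prostate_mask=mask, voxel_area_mm2=0.5)

    def _model(self, beta, intercept):
        return Pls1Model(x_mean=np.zeros(6), x_scale=np.ones(6), y_mean=0.0,
                         w=np.eye(6)[0], p=np.zeros(6), q=0.0,
                         beta=np.asarray(beta, float), intercept=intercept,
                         n_train=10)

    def test_zero_beta_gives_uniform_intercept_map(self):
        dmap = predict_map(self._model(np.zeros(6), 0.4), self._volume())
        np.testing.assert_allclose(dmap.data, 0.4)

    def test_out_of_range_predictions_are_clipped(self):
        dmap = predict_map(self._model(np.zeros(6), 1.3), self._volume())
        np.testing.assert_allclose(dmap.data, 1.0)
        dmap = predict_map(self._model(np.zeros(6), -0.2), self._volume())
        np.testing.assert_allclose(dmap.data, 0.0)

    def test_feature_name_mismatch_is_an_error(self):
        model = self._model(np.zeros(6), 0.5)
        model.feature_names = tuple(reversed(FEATURE_NAMES))
        with pytest.raises(ValueError, match="feature order mismatch"):
            predict_map(model, self._volume())

    def test_outside_mask_is_nan(self):
        vol = self._volume()
        vol.prostate_mask[0, :] = False
        dmap = predict_map(self._model(np.zeros(6), 0.4), vol)
        assert np.isnan(dmap.data[0]).all()
        assert np.isfinite(dmap.data[1:]).all()

    def test_noiseless_phantom_prediction_correlates_with_truth(self):
        cfg = quiet_config(n_patients=1, slides_per_patient=1, seed=41,
                           density_sd=0.02, lesion_count_mean=4.0)
        slide = generate_cohort(cfg)[0]
        mask = slide.prostate_mask
        X = slide.features.data[mask]
        y = slide.truth_density.data[mask]
        model = fit_pls1(X, y)
        pred = predict_map(model, slide.features)
        rho = np.corrcoef(pred.data[mask], y)[0, 1]
        assert rho > 0.95


class TestConsensusAndRoi:
    def test_identical_maps_pass_through(self):
        m = DensityMap(np.full((10, 10), 0.3))
        cons = consensus_map([m, m, m])
        np.testing.assert_array_equal(cons.data, m.data)

    def test_mean_of_constants(self):
        cons = consensus_map([DensityMap(np.full((5, 5), 0.2)),
                              DensityMap(np.full((5, 5), 0.6))])
        np.testing.assert_allclose(cons.data, 0.4)

    def test_matches_loop_oracle_and_mask_intersection(self):
        rng = np.random.default_rng(10)
        maps = []
        for i in range(3):
            data = rng.uniform(size=(8, 8))
            data[i, i] = np.nan  # each map missing one voxel
            maps.append(DensityMap(data))
        cons = consensus_map(maps)
        for r in range(8):
            for c in range(8):
                vals = [m.data[r, c] for m in maps]
                if any(np.isnan(v) for v in vals):
                    assert np.isnan(cons.data[r, c])
                else:
                    assert cons.data[r, c] == pytest.approx(
                        sum(vals) / 3, abs=1e-12)

    def test_shape_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="shape"):
            consensus_map([DensityMap(np.zeros((5, 5))),
                           DensityMap(np.zeros((6, 6)))])

    def test_roi_prediction_median(self):
        labels = np.zeros((30, 30), dtype=np.int16)
        labels[0:15, 0:15] = 3
        lesion = extract_lesions(labels, np.ones((30, 30), bool))[0]
        assert roi_prediction(DensityMap(np.full((30, 30), 0.7)), lesion) == 0.7
        rng = np.random.default_rng(11)
        data = rng.uniform(size=(30, 30))
        expected = float(np.median([data[r, c] for r, c in
                                    zip(lesion.rows, lesion.cols)]))
        assert roi_prediction(DensityMap(data), lesion) == pytest.approx(
            expected, abs=1e-14)


def test_parameter_recovery_heldout_rmse_below_two_percent():
    """Noise-free phantom with a linear feature model: a PLS map trained on
    one set of slides recovers held-out lesion densities to < 0.02."""
    from rpmap.cohort import consensus_unlabeled_rois
    from rpmap.phantom import annotate_cohort, default_annotator_profiles
    from rpmap import build_training_table

    cfg = quiet_config(n_patients=4, slides_per_patient=2, seed=51,
                       density_sd=0.01, lesion_count_mean=4.0)
    slides = generate_cohort(cfg)
    annotate_cohort(slides, default_annotator_profiles(1), seed=cfg.seed)
    train, test = slides[:6], slides[6:]

    def rows(subset):
        tables = []
        for s in subset:
            obs = s.annotations.observers[0]
            lesions = extract_lesions(s.annotations[obs], s.prostate_mask,
                                      min_area_vox=50)
            lesions += consensus_unlabeled_rois(s.annotations, s.prostate_mask,
                                                k=4)
            tables.append(build_training_table(lesions, s.features,
                                               s.truth_density))
        import pandas as pd
        return pd.concat(tables, ignore_index=True)

    tr, te = rows(train), rows(test)
    cols = [f"x_{n}" for n in FEATURE_NAMES]
    model = fit_pls1(tr[cols].to_numpy(), tr["y"].to_numpy())
    resid = model.predict(te[cols].to_numpy()) - te["y"].to_numpy()
    assert np.sqrt(np.mean(resid ** 2)) < 0.02
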