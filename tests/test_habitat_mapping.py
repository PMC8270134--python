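"""Two-step land-cover mapping: balancing, classifiers, aggregation, metrics."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, r2_score

import rewildmap as rw
from rewildmap.geodata_io import NODATA_FLOAT, NODATA_LABEL


def _labels_from_confusion(cm):
    """Expand a confusion matrix cm[pred, obs] into label vectors."""
    pred, obs = [], []
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            pred += [i] * cm[i, j]
            obs += [j] * cm[i, j]
    return np.array(pred), np.array(obs)


class TestMetrics:
    def test_overall_accuracy_counting(self):
        a = np.arange(10)
        b = a.copy()
        b[:3] += 100
        assert rw.overall_accuracy(a, a) == 1.0
        assert rw.overall_accuracy(b, a) == pytest.approx(0.7)
        assert rw.overall_accuracy(a + 50, a) == 0.0

    def test_kappa_hand_derived_confusion(self):
        # cm [[4,1],[2,3]]: p_o = 0.7, p_e = 0.5, kappa = 0.4
        pred, obs = _labels_from_confusion(np.array([[4, 1], [2, 3]]))
        assert rw.cohens_kappa(pred, obs) == pytest.approx(0.4)

    def test_kappa_perfect_and_chance(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 2000)
        assert rw.cohens_kappa(a, a) == pytest.approx(1.0)
        shuffled = rng.permutation(a)
        assert abs(rw.cohens_kappa(shuffled, a)) < 0.1

    def test_kappa_matches_sklearn(self):
        rng = np.random.default_rng(3)
        pred = rng.integers(0, 4, 500)
        obs = rng.integers(0, 4, 500)
        assert rw.cohens_kappa(pred, obs) == pytest.approx(cohen_kappa_score(pred, obs))

    def test_kappa_degenerate_marginals(self):
        ones = np.ones(5)
        assert rw.cohens_kappa(ones, ones) == 1.0

    def test_kappa_accuracy_relation_balanced_symmetric(self):
        # balanced classes with symmetric errors: kappa = (p_o - 1/k)/(1 - 1/k)
        pred, obs = _labels_from_confusion(np.array([[8, 2], [2, 8]]))
        p_o = rw.overall_accuracy(pred, obs)
        assert rw.cohens_kappa(pred, obs) == pytest.approx((p_o - 0.5) / 0.5)

    def test_r_squared_examples(self):
        assert rw.r_squared([1.0, 2, 3], [1.0, 2, 3]) == 1.0
        obs = np.array([1.0, 2, 3])
        assert rw.r_squared(np.full(3, obs.mean()), obs) == pytest.approx(0.0)
        assert rw.r_squared([1.0, 2, 4], [1.0, 2, 3]) == pytest.approx(0.5)

    def test_r_squared_matches_sklearn(self):
        rng = np.random.default_rng(4)
        obs = rng.normal(size=100)
        pred = obs + rng.normal(0, 0.5, 100)
        assert rw.r_squared(pred, obs) == pytest.approx(r2_score(obs, pred))

    def test_r_squared_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero variance"):
            out = rw.r_squared([1.0, 2.0], [3.0, 3.0])
        assert np.isnan(out)

    def test_length_mismatch_errors(self):
        for fn in (rw.overall_accuracy, rw.cohens_kappa, rw.r_squared):
            with pytest.raises(ValueError):
                fn([1, 2, 3], [1, 2])


class TestBalanceTrainingPixels:
    def test_counts_move_to_median(self):
        labels = np.array(["A"] * 100 + ["B"] * 10 + ["C"] * 4)
        feats = np.arange(114, dtype=float)[:, None]
        bl, bf = rw.balance_training_pixels(labels, feats, seed=0)
        _, counts = np.unique(bl, return_counts=True)
        assert list(counts) == [10, 10, 10]  # median of {100, 10, 4}

    def test_downsampling_without_replacement(self):
        labels = np.array(["A"] * 100 + ["B"] * 10 + ["C"] * 4)
        feats = np.arange(114, dtype=float)[:, None]
        bl, bf = rw.balance_training_pixels(labels, feats, seed=1)
        a_feats = bf[bl == "A"].ravel()
        assert len(np.unique(a_feats)) == len(a_feats)

    def test_equal_counts_fixed_point(self):
        labels = np.repeat(["A", "B"], 20)
        feats = np.zeros((40, 2))
        bl, _ = rw.balance_training_pixels(labels, feats, seed=0)
        _, counts = np.unique(bl, return_counts=True)
        assert list(counts) == [20, 20]

    def test_deterministic_given_seed(self):
        labels = np.array(["A"] * 30 + ["B"] * 5)
        feats = np.arange(35, dtype=float)[:, None]
        out1 = rw.balance_training_pixels(labels, feats, seed=7)
        out2 = rw.balance_training_pixels(labels, feats, seed=7)
        assert np.array_equal(out1[1], out2[1])

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            rw.balance_training_pixels(np.array(["A"] * 5), np.zeros((5, 1)), 0)


def _separable_image(n_side=40, noise=0.01, seed=0):
    """Two-class scene: class 3 (forest) band1~0, class 7 (tall grass) band1~1."""
    g = rw.GridSpec(0.0, n_side * 10.0, 10.0, n_side, n_side)
    rng = np.random.default_rng(seed)
    labels = np.where(np.arange(n_side * n_side).reshape(n_side, n_side) % 2 == 0, 3, 7)
    bands = np.where(labels == 3, 0.0, 1.0)[None] + rng.normal(0, noise, (2, n_side, n_side))
    return rw.HabitatMap(g, labels), rw.SpectralImage(g, bands)


@pytest.fixture(scope="module")
def separable_fit():
    hm, img = _separable_image()
    r, c = np.nonzero(np.ones(hm.grid.shape, bool))
    pick = np.random.default_rng(0).choice(len(r), 1000, replace=False)
    cfg = rw.ClassifierConfig(seed=0)
    clf = rw.fit_fine_classifier(img, (hm.labels[r[pick], c[pick]], r[pick], c[pick]), cfg)
    return hm, img, clf


class TestFineClassifier:
    def test_separable_validation_accuracy(self, separable_fit):
        _, _, clf = separable_fit
        assert clf.report.overall_accuracy >= 0.99

    def test_probabilities_sum_to_one(self, separable_fit):
        _, _, clf = separable_fit
        proba = clf.predict_proba(np.random.default_rng(1).normal(size=(50, 2)))
        assert np.abs(proba.sum(axis=1) - 1).max() < 1e-5

    def test_resubstitution_on_separable_scene(self, separable_fit):
        hm, img, clf = separable_fit
        pred = rw.classify_fine(clf, img)
        assert np.mean(pred.labels == hm.labels) >= 0.99

    def test_shuffled_labels_give_chance_kappa(self):
        hm, img = _separable_image(n_side=20)
        r, c = np.nonzero(np.ones(hm.grid.shape, bool))
        labels = hm.labels[r, c]
        kappas = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            shuffled = rng.permutation(labels)
            cfg = rw.ClassifierConfig(seed=seed, epochs=50)
            clf = rw.fit_fine_classifier(img, (shuffled, r, c), cfg)
            kappas.append(clf.report.kappa)
        assert np.max(np.abs(kappas)) < 0.15

    def test_nodata_propagated(self, separable_fit):
        hm, img, clf = separable_fit
        masked = rw.SpectralImage(img.grid, np.full_like(img.bands, NODATA_FLOAT))
        out = rw.classify_fine(clf, masked)
        assert (out.labels == NODATA_LABEL).all()

    def test_band_mismatch_errors(self, separable_fit):
        _, img, clf = separable_fit
        g = img.grid
        bad = rw.SpectralImage(g, np.zeros((3, g.n_rows, g.n_cols)))
        with pytest.raises(ValueError, match="band"):
            rw.classify_fine(clf, bad)

    def test_too_few_pixels_per_class_errors(self):
        hm, img = _separable_image(n_side=10)
        labels = np.array([3] * 8 + [7] * 8)
        r = np.arange(16) // 4
        c = np.arange(16) % 4
        with pytest.raises(ValueError, match="10 pixels"):
            rw.fit_fine_classifier(img, (labels, r, c), rw.ClassifierConfig(seed=0))


class TestAggregateProportions:
    def test_block_counting(self):
        g = rw.GridSpec(0.0, 30.0, 10.0, 3, 3)
        labels = np.array([[3, 3, 3], [3, 3, 3], [7, 7, 7]])
        pr = rw.aggregate_proportions(rw.HabitatMap(g, labels), 3)
        assert pr.band("broadleaf forest")[0, 0] == pytest.approx(2 / 3)
        assert pr.band("tall grassland")[0, 0] == pytest.approx(1 / 3)

    def test_uniform_map_one_hot(self):
        g = rw.GridSpec(0.0, 60.0, 10.0, 6, 6)
        pr = rw.aggregate_proportions(rw.HabitatMap(g, np.full((6, 6), 9)), 3)
        assert np.all(pr.band("water") == 1.0)
        assert pr.fractions.sum(axis=0).max() == pytest.approx(1.0)

    def test_checkerboard_half_half(self):
        g = rw.GridSpec(0.0, 80.0, 10.0, 8, 8)
        labels = (np.indices((8, 8)).sum(axis=0) % 2) * 4 + 3  # 3 / 7 checkerboard
        pr = rw.aggregate_proportions(rw.HabitatMap(g, labels), 2)
        assert np.all(pr.band("broadleaf forest") == 0.5)
        assert np.all(pr.band("tall grassland") == 0.5)

    def test_nodata_majority_rule(self):
        g = rw.GridSpec(0.0, 20.0, 10.0, 2, 2)
        labels = np.array([[3, NODATA_LABEL], [NODATA_LABEL, NODATA_LABEL]])
        pr = rw.aggregate_proportions(rw.HabitatMap(g, labels), 2)
        assert pr.nodata_mask[0, 0]  # 3 of 4 fine cells are NODATA

    def test_area_conservation(self, habitat):
        pr = rw.aggregate_proportions(habitat, 2)
        coarse_area = pr.grid.cell_area_m2
        for name in ("tall grassland", "broadleaf forest"):
            fine = habitat.class_mask(name).sum() * habitat.grid.cell_area_m2
            coarse = pr.band(name)[~pr.nodata_mask].sum() * coarse_area
            assert coarse == pytest.approx(fine, abs=coarse_area)

    def test_bad_factor_errors(self, habitat):
        with pytest.raises(ValueError):
            rw.aggregate_proportions(habitat, 0)


@pytest.fixture(scope="module")
def mixture_fit():
    # coarse bands are exact linear mixtures of two class signatures
    g = rw.GridSpec(0.0, 600.0, 30.0, 20, 20)
    rng = np.random.default_rng(0)
    frac_forest = rng.uniform(0, 1, (20, 20))
    sig_forest = np.array([0.1, 0.8])
    sig_grass = np.array([0.7, 0.2])
    bands = (frac_forest[None] * sig_forest[:, None, None]
             + (1 - frac_forest)[None] * sig_grass[:, None, None])
    img = rw.SpectralImage(g, bands)
    cat = rw.ClassCatalogue()
    fr = np.zeros((len(cat), 20, 20))
    fr[cat.index("broadleaf forest")] = frac_forest
    fr[cat.index("tall grassland")] = 1 - frac_forest
    targets = rw.ProportionRaster(g, fr, cat)
    cfg = rw.ClassifierConfig.coarse(seed=0)
    cfg.batch_size = 64
    return rw.fit_proportion_regressor(img, targets, cfg), img, targets


class TestProportionRegressor:
    def test_linear_mixture_r2(self, mixture_fit):
        reg, _, _ = mixture_fit
        assert reg.report.r2_overall >= 0.95

    def test_predictions_on_simplex(self, mixture_fit):
        reg, img, _ = mixture_fit
        pred = reg.predict(np.random.default_rng(1).uniform(0, 1, (30, 2)))
        assert np.abs(pred.sum(axis=1) - 1).max() < 1e-5
        assert pred.min() >= 0

    def test_constant_class_r2_flagged(self, mixture_fit):
        reg, _, _ = mixture_fit
        # classes absent from the mixture have constant (zero) targets
        assert np.isnan(reg.report.r2_per_class["water"])

    def test_grid_mismatch_errors(self, mixture_fit):
        _, img, targets = mixture_fit
        g2 = rw.GridSpec(0.0, 300.0, 30.0, 10, 10)
        bad = rw.SpectralImage(g2, np.zeros((2, 10, 10)))
        with pytest.raises(ValueError, match="grid"):
            rw.fit_proportion_regressor(bad, targets, rw.ClassifierConfig.coarse(0))


def test_two_step_pipeline_recovers_true_proportions():
    """Noiseless scene: full two-step cover estimate within 0.05 MAE per class."""
    g = rw.GridSpec(0.0, 600.0, 10.0, 60, 60)
    weights = {"tall grassland": 0.6, "broadleaf forest": 0.4}
    truth = rw.make_landscape(rw.LandscapeConfig(g, weights, 100.0, seed=5))
    sigs = {"tall grassland": [0.7, 0.2, 0.1], "broadleaf forest": [0.1, 0.8, 0.3]}
    img = rw.make_spectra(truth, sigs, noise_sd=0.005, seed=5)

    r, c = np.nonzero(np.ones(g.shape, bool))
    pick = np.random.default_rng(5).choice(len(r), 1500, replace=False)
    clf = rw.fit_fine_classifier(
        img, (truth.labels[r[pick], c[pick]], r[pick], c[pick]), rw.ClassifierConfig(seed=5))
    fine = rw.classify_fine(clf, img)
    est = rw.aggregate_proportions(fine, 3)
    ref = rw.aggregate_proportions(truth, 3)
    for name in weights:
        mae = np.abs(est.band(name) - ref.band(name)).mean()
        assert mae < 0.05
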