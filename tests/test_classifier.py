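"""Segmentation, preprocessing, feature learning and cross-validation."""

import numpy as np
import pytest

from cspws.classifier import (Autoencoder, DEFAULT_RF_GRID, FeatureMatrix,
                              RandomConvFeatures,
                              build_feature_matrix, cross_validate,
                              evaluate_endpoints, extract_features,
                              fit_classifier, optimal_cutpoint, preprocess,
                              segment_nuclei, train_autoencoder)
from cspws.exceptions import InsufficientDataError, ModelConfigError
from cspws.synth import (gen_cohort, gen_cohort_images, gen_nucleus_masks,
                         two_group_spec)

TINY_GRID = {"n_estimators": [30], "max_depth": [None, 3]}


def small_feature_matrix(shift=2.5, n_per_group=8, cells=31, seed=0):
    coh = gen_cohort(two_group_spec(shift, n_per_group=n_per_group,
                                    cells_per_patient=cells, seed=seed))
    imgs = gen_cohort_images(coh, size=24, seed=seed + 1)
    return build_feature_matrix(imgs)


class TestSegmentation:
    def test_mask_path_counts_and_areas(self):
        mask, ellipses = gen_nucleus_masks(5, (128, 128), seed=3)
        values = np.where(mask > 0, 2.5, np.nan)
        crops = segment_nuclei(values, mask=mask, patient_id="p1")
        assert len(crops) == 5
        for crop, e in zip(crops, ellipses):
            assert np.isfinite(crop.pixels).sum() == (mask == e.label).sum()

    def test_mask_path_ignores_background_values(self):
        mask, _ = gen_nucleus_masks(3, (96, 96), seed=4)
        rng = np.random.default_rng(0)
        values = rng.normal(2.5, 0.1, mask.shape)
        a = segment_nuclei(values, mask=mask)
        noisy_bg = values.copy()
        noisy_bg[mask == 0] = 1e9
        b = segment_nuclei(noisy_bg, mask=mask)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(
                np.nan_to_num(ca.pixels), np.nan_to_num(cb.pixels))

    def test_threshold_path_finds_disks(self):
        img = np.zeros((128, 128))
        yy, xx = np.mgrid[0:128, 0:128]
        for cy, cx in [(30, 30), (30, 90), (90, 60)]:
            img[(yy - cy) ** 2 + (xx - cx) ** 2 <= 12 ** 2] = 2.6
        crops = segment_nuclei(img, min_area=100)
        assert len(crops) == 3

    def test_blank_dmap_gives_empty_list(self):
        with pytest.warns(UserWarning):
            assert segment_nuclei(np.full((32, 32), np.nan)) == []


class TestPreprocess:
    def test_minmax_mapping(self):
        img = np.array([[2.0, 2.5], [3.0, 2.0]])
        out = preprocess(img, out_size=(2, 2))
        assert out[0, 1] == pytest.approx(0.5)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_constant_input_maps_to_zeros(self):
        out = preprocess(np.full((8, 8), 2.4), out_size=(16, 16))
        assert np.all(out == 0.0)

    def test_output_range_for_random_inputs(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            img = rng.normal(2.5, 0.2, (19, 23))
            out = preprocess(img, out_size=(32, 32))
            assert out.min() == pytest.approx(0.0)
            assert out.max() == pytest.approx(1.0)
            assert out.shape == (32, 32)

    def test_degenerate_crop_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.array([[2.0]]))


class TestExtractor:
    def test_deterministic_and_dimension(self):
        ex = RandomConvFeatures()
        rng = np.random.default_rng(6)
        img = rng.uniform(0, 1, (32, 32))
        v1 = extract_features(img, ex)
        v2 = extract_features(img, ex)
        np.testing.assert_array_equal(v1, v2)
        assert v1.shape == (ex.n_features,) == (512,)

    def test_declared_dimension_enforced(self):
        class Broken:
            extractor_id = "broken"
            n_features = 9
            input_size = 32
            def __call__(self, image):
                return np.zeros(4)
        with pytest.raises(ModelConfigError, match="broken"):
            extract_features(np.zeros((32, 32)), Broken())

    def test_offset_invariance_through_pipeline(self):
        rng = np.random.default_rng(7)
        ex = RandomConvFeatures()
        img = rng.normal(2.5, 0.1, (24, 24))
        v1 = extract_features(preprocess(img, (32, 32)), ex)
        v2 = extract_features(preprocess(img + 0.2, (32, 32)), ex)
        np.testing.assert_allclose(v1, v2, atol=1e-5)


class TestAutoencoder:
    def test_loss_decreases(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(300, 30)).astype(np.float32)
        ae, log = train_autoencoder(x, code_dim=4, seed=0, epochs=30)
        assert log["final_loss"] <= log["initial_loss"]

    def test_low_rank_inputs_reconstructed(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((400, 5)) @ rng.standard_normal((5, 40))
        ae, _ = train_autoencoder(x, code_dim=8, seed=1, epochs=200,
                                  patience=20)
        mse = np.mean((ae.reconstruct(x) - x) ** 2)
        assert mse <= 0.01 * np.var(x)

    def test_seed_determinism(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(200, 20)).astype(np.float32)
        a, _ = train_autoencoder(x, code_dim=4, seed=3, epochs=15)
        b, _ = train_autoencoder(x, code_dim=4, seed=3, epochs=15)
        np.testing.assert_array_equal(a.encode(x), b.encode(x))

    def test_code_dim_too_large_rejected(self):
        with pytest.raises(ModelConfigError):
            Autoencoder(input_dim=16, code_dim=16)


class TestFitClassifier:
    def test_separable_clusters_perfect_training_auc(self):
        rng = np.random.default_rng(11)
        codes = np.vstack([rng.normal(-3, 0.2, (40, 4)),
                           rng.normal(3, 0.2, (40, 4))])
        labels = np.array([0] * 40 + [1] * 40)
        model, cfg = fit_classifier(codes, labels, grid=TINY_GRID, seed=0)
        from sklearn.metrics import roc_auc_score
        assert roc_auc_score(labels,
                             model.predict_proba(codes)[:, 1]) == 1.0

    def test_chosen_config_in_declared_grid(self):
        rng = np.random.default_rng(12)
        codes = rng.normal(size=(60, 4))
        labels = rng.integers(0, 2, 60)
        _, cfg = fit_classifier(codes, labels, grid=DEFAULT_RF_GRID, seed=0)
        for key, val in cfg.items():
            assert val in DEFAULT_RF_GRID[key]

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(13)
        from sklearn.metrics import roc_auc_score
        from sklearn.model_selection import cross_val_predict
        from sklearn.ensemble import RandomForestClassifier
        aucs = []
        for seed in range(20):
            codes = rng.normal(size=(120, 4))
            labels = rng.permutation([0] * 60 + [1] * 60)
            prob = cross_val_predict(
                RandomForestClassifier(30, random_state=seed), codes, labels,
                cv=4, method="predict_proba")[:, 1]
            aucs.append(roc_auc_score(labels, prob))
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_single_class_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_classifier(np.zeros((10, 3)), np.zeros(10, dtype=int),
                           grid=TINY_GRID)


class TestCutpoint:
    def test_maximizes_correct_classifications(self):
        rng = np.random.default_rng(14)
        y = rng.integers(0, 2, 30)
        s = rng.uniform(size=30)
        t, sens, spec = optimal_cutpoint(y, s)
        n1, n0 = (y == 1).sum(), (y == 0).sum()
        best = sens * n1 + spec * n0
        for cand in s:
            correct = ((s >= cand) & (y == 1)).sum() + ((s < cand) & (y == 0)).sum()
            assert correct <= best + 1e-9

    def test_tie_broken_toward_lowest_threshold(self):
        y = np.array([0, 1])
        s = np.array([0.2, 0.8])
        t, sens, spec = optimal_cutpoint(y, s)
        assert t == pytest.approx(0.8)  # unique maximizer here
        # symmetric tie: both thresholds classify one right, one wrong
        y2 = np.array([1, 0])
        s2 = np.array([0.2, 0.8])
        t2, _, _ = optimal_cutpoint(y2, s2)
        assert t2 == pytest.approx(0.2)


@pytest.fixture(scope="module")
def fm():
    # a widely separated cohort: the patient-level shift dwarfs all noise
    return small_feature_matrix(shift=6.0)


@pytest.fixture(scope="module")
def cv(fm):
    return cross_validate(fm, n_folds=4, n_repeats=2, seed=0,
                          code_dim=8, grid=TINY_GRID,
                          ae_kwargs={"epochs": 15})


class TestCrossValidate:
    def test_separable_cohort_high_auc(self, cv):
        assert cv.summary["auc"][0] > 0.9

    def test_stratification_within_one_patient(self, cv, fm):
        import pandas as pd
        labels = pd.DataFrame({"patient_id": fm.patient_ids,
                               "label": fm.labels}).drop_duplicates()
        merged = cv.fold_assignments.merge(labels, on="patient_id")
        n_case = (labels.label == "case").sum()
        global_ratio = n_case / len(labels)
        for (_, _), grp in merged.groupby(["repeat", "fold"]):
            expected = global_ratio * len(grp)
            assert abs((grp.label == "case").sum() - expected) <= 1.0

    def test_no_patient_straddles_folds(self, cv):
        per = cv.fold_assignments.groupby(["repeat", "patient_id"])["fold"]
        assert per.nunique().max() == 1

    def test_determinism_bitwise(self, fm, cv):
        again = cross_validate(fm, n_folds=4, n_repeats=2, seed=0,
                               code_dim=8, grid=TINY_GRID,
                               ae_kwargs={"epochs": 15})
        import pandas as pd
        pd.testing.assert_frame_equal(cv.folds, again.folds)
        pd.testing.assert_frame_equal(cv.fold_assignments,
                                      again.fold_assignments)

    def test_missing_label_rejected(self, fm):
        broken = FeatureMatrix(fm.features, fm.patient_ids,
                               np.array([None] * len(fm.labels)))
        with pytest.raises(ValueError, match="no label"):
            cross_validate(broken, n_folds=2, n_repeats=1)

    def test_too_few_patients_per_class(self, fm):
        one_each = np.isin(fm.patient_ids, [fm.patient_ids[0],
                                            fm.patient_ids[-1]])
        with pytest.raises(InsufficientDataError):
            cross_validate(fm.subset(one_each), n_folds=4, n_repeats=1)


class TestEndpoints:
    def test_all_control_mapping_rejected(self):
        fm = small_feature_matrix(n_per_group=4)
        import pandas as pd
        meta = pd.DataFrame({
            "patient_id": np.unique(fm.patient_ids),
            "group": ["control"] * len(np.unique(fm.patient_ids)),
            "lesion_size": None})
        with pytest.raises(ValueError, match="empty class"):
            evaluate_endpoints(fm, meta,
                               {"bad": {"control": ["control"], "case": []}})

    def test_subgroup_counts_match_generated(self):
        coh = gen_cohort(two_group_spec(2.5, n_per_group=8,
                                        cells_per_patient=31, seed=20))
        sizes = {"<1 cm": 0.4, "1-1.5 cm": 0.4, ">1.5 cm": 0.2}
        for g in coh.spec.groups:
            if g.label == "case":
                g.lesion_size_probs = sizes
        coh = gen_cohort(coh.spec)
        imgs = gen_cohort_images(coh, size=24, seed=21)
        fm = build_feature_matrix(imgs)
        meta = coh.to_patient_table()
        out = evaluate_endpoints(
            fm, meta,
            {"main": {"control": ["control"], "case": ["case"]}},
            size_within="main", n_folds=2, n_repeats=1, code_dim=8,
            grid=TINY_GRID, ae_kwargs={"epochs": 10})
        gen_counts = meta.loc[meta.label == "case",
                              "lesion_size"].value_counts()
        sub = out[out.subgroup.notna()].set_index("subgroup")
        for cat, n in gen_counts.items():
            assert sub.loc[cat, "n_case"] == n
        assert "sens_at_fixed_spec" in sub.columns
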