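"""Cascade orchestration: ROI geometry, refinement identities, cross-validation."""

import dataclasses

import numpy as np
import pytest

from cascadeseg import (CascadeConfig, CNNConfig, LabelMap, LabelScheme, PhantomConfig,
                        SVMEnsembleConfig, crossvalidate, fit_pipeline, generate_cohort,
                        load_models, make_roi, run_case, save_models)
from cascadeseg.features import FeatureConfig

TINY_RADII = {"NCR": (1.5, 1.2), "ET": (3.0, 2.2), "NET": (4.5, 3.5), "ED": (6.5, 5.0)}
TINY = PhantomConfig(shape=(32, 32), radii=TINY_RADII, noise_sd=0.2, bias_amplitude=0.1)
TINY_CASCADE = CascadeConfig(
    cnn=CNNConfig(epochs=2, max_train_pixels=1500),
    svm=SVMEnsembleConfig(n_members=2, max_train_pixels=1200),
    seed=0,
)


def _binary(data):
    return LabelMap(data=np.asarray(data, dtype=int), scheme=LabelScheme.BINARY)


class TestMakeRoi:
    def test_empty_presegmentation_empty_roi(self):
        assert not make_roi(_binary(np.zeros((8, 8))), 3).any()

    def test_radius_zero_is_identity(self):
        rng = np.random.default_rng(0)
        fg = rng.integers(0, 2, size=(10, 10))
        np.testing.assert_array_equal(make_roi(_binary(fg), 0), fg.astype(bool))

    def test_unit_disc_is_plus_shape(self):
        fg = np.zeros((5, 5), dtype=int)
        fg[2, 2] = 1
        roi = make_roi(_binary(fg), 1)
        expected = np.zeros((5, 5), dtype=bool)
        expected[2, 1:4] = True
        expected[1:4, 2] = True
        np.testing.assert_array_equal(roi, expected)
        assert roi.sum() == 5

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            make_roi(_binary(np.zeros((4, 4))), -1)

    def test_brats_map_rejected(self):
        m = LabelMap(data=np.array([[0, 2]]), scheme=LabelScheme.BRATS)
        with pytest.raises(ValueError, match="BINARY"):
            make_roi(m, 1)


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [dict(roi_dilation=-1), dict(max_iterations=-1),
                                     dict(convergence_tol=1.5)])
    def test_rejected(self, bad):
        with pytest.raises(ValueError):
            CascadeConfig(**bad)


class TestRefinementIdentities:
    """Identity checks on the session-trained models (study conditions)."""

    def test_zero_iterations_reproduce_presegmentation(
            self, trained_models, test_cases, cascade_config):
        cnn_m, svm_m = trained_models
        cfg = dataclasses.replace(cascade_config, max_iterations=0)
        result = run_case(cnn_m, svm_m, test_cases[0], cfg)
        assert result.iterations_run == 0
        np.testing.assert_array_equal(result.final.data, result.presegmentation.data)

    def test_tolerance_one_runs_exactly_one_iteration(
            self, trained_models, test_cases, cascade_config):
        cnn_m, svm_m = trained_models
        cfg = dataclasses.replace(cascade_config, convergence_tol=1.0, max_iterations=5)
        result = run_case(cnn_m, svm_m, test_cases[0], cfg)
        assert result.iterations_run == 1

    def test_pixels_outside_roi_never_change(self, cascade_results, cascade_config):
        for result in cascade_results:
            previous = result.presegmentation.data
            for refined in result.refined:
                roi = make_roi(_binary(previous), cascade_config.roi_dilation)
                np.testing.assert_array_equal(refined.data[~roi], previous[~roi])
                previous = refined.data

    def test_change_fractions_recomputable_from_maps(self, cascade_results):
        for result in cascade_results:
            assert result.iterations_run <= 2
            assert len(result.per_iteration_change) == result.iterations_run
            previous = result.presegmentation.data
            for refined, change in zip(result.refined, result.per_iteration_change):
                assert change == np.mean(refined.data != previous)
                previous = refined.data
            np.testing.assert_array_equal(result.final.data, result.refined[-1].data
                                          if result.refined else result.presegmentation.data)


class TestPipeline:
    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            fit_pipeline([], TINY_CASCADE)

    def test_model_round_trip_through_container(self, tmp_path, trained_models,
                                                test_cases, cascade_config):
        cnn_m, svm_m = trained_models
        save_models(tmp_path / "models.pkl", cnn_m, svm_m)
        cnn_b, svm_b = load_models(tmp_path / "models.pkl")
        a = run_case(cnn_m, svm_m, test_cases[0], cascade_config)
        b = run_case(cnn_b, svm_b, test_cases[0], cascade_config)
        np.testing.assert_array_equal(a.final.data, b.final.data)

    def test_svm_trained_on_cnn_labels_differs_from_truth_trained(self):
        """The refinement stage must learn from the CNN's mistakes, not from
        an oracle: swapping its label column to the ground truth changes the
        trained ensemble's behavior on a noisy cohort."""
        import cascadeseg.cascade as _c
        from cascadeseg import binarize_whole_tumor
        from cascadeseg.features import augment_with_labels
        from cascadeseg.svm_ensemble import decision_values, train_ensemble
        from cascadeseg import cnn_classifier as _cnn

        cohort = generate_cohort(2, TINY, seed=3)
        cfg = TINY_CASCADE.seeded()
        cnn_m = _cnn.train_cnn(cohort, cfg.cnn)
        tables, targets = [], []
        for case in cohort:
            table = _c._case_feature_table(case, cfg.feature)
            preseg = _cnn.predict_labels(cnn_m, case)
            tables.append((table, preseg, binarize_whole_tumor(case.truth)))
            targets.append(tables[-1][2].data.ravel())
        y = np.concatenate(targets)

        def pooled(label_source):
            rows = [augment_with_labels(t, label_source(i)) for i, (t, _, _) in
                    enumerate(tables)]
            feats = np.vstack([r.features for r in rows])
            from cascadeseg.features import PixelFeatureTable
            return PixelFeatureTable(coords=np.zeros((feats.shape[0], 1), dtype=int),
                                     features=feats)

        on_cnn = train_ensemble(pooled(lambda i: tables[i][1]), y, cfg.svm)
        on_truth = train_ensemble(pooled(lambda i: tables[i][2]), y, cfg.svm)
        probe = pooled(lambda i: tables[i][1])
        assert not np.array_equal(decision_values(on_cnn, probe),
                                  decision_values(on_truth, probe))


@pytest.fixture(scope="module")
def tiny_cohort():
    return generate_cohort(3, TINY, seed=1)


class TestCrossValidation:

    def test_leave_one_out_partition(self, tiny_cohort):
        reports = crossvalidate(tiny_cohort, TINY_CASCADE, k=3)
        assert len(reports) == 3
        assert all(r.n_cases == 1 for r in reports)
        tested = sorted(row[0] for r in reports for row in r.per_case)
        assert tested == sorted(c.case_id for c in tiny_cohort)

    def test_fold_assignment_reproducible(self, tiny_cohort):
        a = crossvalidate(tiny_cohort, TINY_CASCADE, k=2)
        b = crossvalidate(tiny_cohort, TINY_CASCADE, k=2)
        assert [[row[0] for row in r.per_case] for r in a] == \
            [[row[0] for row in r.per_case] for r in b]

    def test_k_exceeding_cases_rejected(self, tiny_cohort):
        with pytest.raises(ValueError, match="k=4"):
            crossvalidate(tiny_cohort, TINY_CASCADE, k=4)
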