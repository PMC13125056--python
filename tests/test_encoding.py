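"""Ridge encoding: closed form, lambda selection, layer curves, ceilings."""

import numpy as np
import pytest
from sklearn.linear_model import Ridge as SkRidge

from midvision.annotations import prepare_design_matrices
from midvision.encoding import (
    EncodingConfig,
    default_lambda_grid,
    encode_eeg,
    encode_layers,
    fit_ridge,
    noise_ceiling,
    pearson_columns,
    predict_ridge,
    prepare_layer_activations,
    select_lambda,
    weighted_mean_correlation,
)
from midvision.simulate import (
    ForwardModelSpec,
    LayerModelSpec,
    simulate_eeg,
    simulate_layer_activations,
)


class TestRidge:
    def test_small_lambda_equals_least_squares(self, rng):
        X = rng.standard_normal((50, 6))
        Y = rng.standard_normal((50, 3))
        model = fit_ridge(X, Y, 1e-10)
        Xi = np.column_stack([np.ones(50), X])
        beta, *_ = np.linalg.lstsq(Xi, Y, rcond=None)
        assert np.abs(model.weights - beta[1:]).max() < 1e-6
        assert np.abs(model.intercept - beta[0]).max() < 1e-6

    def test_matches_sklearn_ridge(self, rng):
        """Independent oracle: sklearn's solver on the same penalty."""
        X = rng.standard_normal((40, 7))
        Y = rng.standard_normal((40, 2))
        for lam in (0.5, 10.0, 1e4):
            model = fit_ridge(X, Y, lam)
            sk = SkRidge(alpha=lam).fit(X, Y)
            assert np.allclose(model.weights, sk.coef_.T, atol=1e-8)
            assert np.allclose(model.intercept, sk.intercept_, atol=1e-8)

    def test_infinite_shrinkage_predicts_training_mean(self, rng):
        X = rng.standard_normal((30, 4))
        Y = rng.standard_normal((30, 2)) + 5
        model = fit_ridge(X, Y, 1e15)
        assert np.abs(model.weights).max() < 1e-10
        pred = predict_ridge(model, rng.standard_normal((5, 4)))
        assert np.allclose(pred, Y.mean(axis=0), atol=1e-8)

    def test_exact_linear_data_recovered(self, rng):
        X = rng.standard_normal((60, 5))
        beta_true = rng.standard_normal((5, 3))
        Y = X @ beta_true
        model = fit_ridge(X, Y, 1e-10)
        assert np.abs(model.weights - beta_true).max() < 1e-6

    def test_negative_lambda_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_ridge(rng.standard_normal((10, 2)), rng.standard_normal((10, 1)), -1.0)

    def test_nan_inputs_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_ridge(X, rng.standard_normal((10, 1)), 1.0)


class TestLambdaSelection:
    def test_default_grid_geometry(self):
        grid = default_lambda_grid()
        assert len(grid) == 30
        assert np.isclose(grid[0], 1e-5) and np.isclose(grid[-1], 1e15)
        assert np.allclose(np.diff(np.log10(grid)), np.diff(np.log10(grid))[0])

    def test_noiseless_validation_picks_smallest_lambda(self, rng):
        X = rng.standard_normal((80, 6))
        beta = rng.standard_normal((6, 4))
        Xv = rng.standard_normal((40, 6))
        lam, scores = select_lambda(X, X @ beta, Xv, Xv @ beta)
        assert lam == default_lambda_grid()[0]
        assert scores[0] > scores[-1]

    def test_single_value_grid_returns_it(self, rng):
        X = rng.standard_normal((20, 3))
        Y = rng.standard_normal((20, 2))
        lam, _ = select_lambda(X, Y, X, Y, grid=np.array([7.5]))
        assert lam == 7.5

    def test_constant_validation_column_warns_and_scores_zero(self, rng):
        X = rng.standard_normal((20, 3))
        Y = rng.standard_normal((20, 2))
        Yv = np.zeros((10, 2))
        with pytest.warns(RuntimeWarning, match="constant"):
            lam, scores = select_lambda(X, Y, rng.standard_normal((10, 3)), Yv)
        assert np.allclose(scores, 0)
        assert lam == default_lambda_grid()[0]  # tie -> smallest

    def test_empty_grid_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(ValueError):
            select_lambda(X, X, X, X, grid=np.array([]))


class TestWeightedCorrelation:
    def test_equal_weights_reduce_to_mean(self, rng):
        r = rng.random(6)
        assert np.isclose(weighted_mean_correlation(r, np.ones(6)), r.mean())

    def test_worked_example(self):
        assert weighted_mean_correlation(
            np.array([0.9, 0.3]), np.array([2.0, 1.0])
        ) == pytest.approx(0.7)

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_mean_correlation(np.array([0.5]), np.array([0.0]))


class TestEncodeEEG:
    @pytest.fixture(scope="class")
    def setup(self, small_design, small_annotations):
        spec = ForwardModelSpec(reps={"train": 4, "test": 6, "validation": 4}, seed=13)
        eeg = simulate_eeg(small_design, small_annotations, spec)
        mats = prepare_design_matrices(small_annotations, small_design)
        acc = encode_eeg(
            mats,
            eeg.select_split("train"),
            eeg.select_split("validation"),
            eeg.select_split("test"),
        )
        return small_design, small_annotations, spec, eeg, mats, acc

    def test_accuracy_bounded_and_shaped(self, setup):
        *_, spec, eeg, mats, acc = setup
        for f, surface in acc.surfaces.items():
            assert surface.shape == (spec.n_channels, spec.n_timepoints)
            assert np.all(surface >= -1) and np.all(surface <= 1)

    def test_planted_latency_recovered_within_one_sample(self, setup):
        *_, spec, eeg, mats, acc = setup
        for f in spec.features:
            curve = acc.timecourses[f.name]
            peak = acc.time_ms[np.argmax(curve)]
            assert abs(peak - f.tau_ms) <= 20.0, f.name

    def test_prestimulus_accuracy_near_zero(self, setup):
        *_, acc = setup
        for f, curve in acc.timecourses.items():
            assert np.abs(curve[acc.time_ms < 0]).mean() < 0.1

    def test_lambda_selection_ignores_test_data(self, small_design, small_annotations):
        """Leakage check: perturbing test responses never changes lambda*."""
        spec = ForwardModelSpec(reps={"train": 3, "test": 2, "validation": 3}, seed=19)
        eeg = simulate_eeg(small_design, small_annotations, spec)
        mats = prepare_design_matrices(small_annotations, small_design)
        test = eeg.select_split("test")
        perturbed = test.copy()
        perturbed.data = perturbed.data + 50.0 * np.random.default_rng(0).standard_normal(
            perturbed.data.shape
        )
        a = encode_eeg(mats, eeg.select_split("train"), eeg.select_split("validation"), test)
        b = encode_eeg(
            mats, eeg.select_split("train"), eeg.select_split("validation"), perturbed
        )
        assert a.selected_lambda == b.selected_lambda

    def test_shuffled_predictors_score_near_zero(self, setup):
        design, ann, spec, eeg, mats, _ = setup
        rng = np.random.default_rng(3)
        shuffled_mats = prepare_design_matrices(ann, design)
        for f in shuffled_mats.features():
            for split in shuffled_mats.matrices[f]:
                m = shuffled_mats.matrices[f][split]
                shuffled_mats.matrices[f][split] = m[rng.permutation(len(m))]
        acc = encode_eeg(
            shuffled_mats,
            eeg.select_split("train"),
            eeg.select_split("validation"),
            eeg.select_split("test"),
        )
        for f, curve in acc.timecourses.items():
            assert np.abs(curve).mean() < 0.1

    def test_missing_split_rejected(self, setup):
        design, ann, spec, eeg, mats, _ = setup
        broken = prepare_design_matrices(ann, design)
        del broken.matrices["edges"]["validation"]
        with pytest.raises(ValueError, match="missing split"):
            encode_eeg(
                broken,
                eeg.select_split("train"),
                eeg.select_split("validation"),
                eeg.select_split("test"),
            )


class TestEncodeLayers:
    def test_planted_peak_layers_recovered(self, small_design, small_annotations):
        acts = simulate_layer_activations(
            small_design, small_annotations, LayerModelSpec(units_per_layer=80, seed=23)
        )
        mats = prepare_design_matrices(small_annotations, small_design)
        prepared = prepare_layer_activations(acts, small_design)
        assert all(
            np.cumsum(ev)[-1] / ev.sum() >= 0.0 for ev in prepared.explained_variance.values()
        )
        curves, lambdas = encode_layers(mats, prepared)
        from midvision.simulate import default_features

        for f in default_features():
            peak = prepared.layer_labels[int(np.argmax(curves[f.name]))]
            assert peak == f.peak_layer, f.name

    def test_variance_threshold_honored(self, small_design, small_annotations, rng):
        acts = {
            "1.0": rng.standard_normal((len(small_design), 40)) * np.arange(1, 41)
        }
        prepared = prepare_layer_activations(acts, small_design, variance_threshold=0.9)
        ev = prepared.explained_variance["1.0"]
        train = acts["1.0"][(small_design["split"] == "train").to_numpy()]
        total = train.var(axis=0, ddof=1).sum()
        assert ev.sum() / total >= 0.9
        assert (ev[:-1].sum() / total) < 0.9  # minimal component count

    def test_missing_weights_rejected(self, small_design, small_annotations):
        acts = simulate_layer_activations(
            small_design, small_annotations, LayerModelSpec(units_per_layer=10, seed=2)
        )
        mats = prepare_design_matrices(small_annotations, small_design)
        prepared = prepare_layer_activations(acts, small_design)
        del prepared.explained_variance["1.0"]
        with pytest.raises(ValueError, match="explained-variance"):
            encode_layers(mats, prepared)


class TestNoiseCeiling:
    def test_noiseless_repetitions_reach_one(self, small_design, small_annotations):
        spec = ForwardModelSpec(
            noise_scale=0.0, reps={"train": 2, "test": 4, "validation": 2}, seed=29
        )
        eeg = simulate_eeg(small_design, small_annotations, spec).select_split("test")
        nc = noise_ceiling(eeg, n_reps=5, seed=1)
        post = eeg.time_ms >= 60  # evoked window (kernels are onset-gated)
        assert np.nanmin(nc.lower[:, post]) > 0.99
        assert np.nanmin(nc.upper[:, post]) > 0.99

    def test_stimulus_independent_responses_give_zero_ceiling(self, rng):
        from tests_helpers import toy_epochs

        data = rng.standard_normal((240, 4, 6))
        epochs = toy_epochs(data, stimulus_ids=np.repeat(np.arange(60), 4), split="test")
        nc = noise_ceiling(epochs, n_reps=20, seed=2)
        # |r| of a null correlation over 60 stimuli ~ 0.8/sqrt(59) ~ 0.10
        assert np.abs(nc.lower).mean() < 0.15
        # the half group is contained in the all-trial group, so the upper
        # bound converges to sqrt(1/2) under pure noise, not to 0
        assert abs(nc.upper.mean() - np.sqrt(0.5)) < 0.1

    def test_upper_bound_at_least_lower(self, small_eeg):
        nc = noise_ceiling(small_eeg.select_split("test"), n_reps=10, seed=3)
        assert (nc.upper >= nc.lower - 0.05).all()

    def test_encoding_accuracy_below_lower_ceiling_in_signal_window(
        self, small_design, small_annotations
    ):
        # the ceiling property needs the full test repetition count: the lower
        # bound is a half-vs-half correlation, the encoding target an
        # all-repetition average
        spec = ForwardModelSpec(reps={"train": 4, "test": 30, "validation": 4}, seed=13)
        eeg = simulate_eeg(small_design, small_annotations, spec)
        mats = prepare_design_matrices(small_annotations, small_design)
        acc = encode_eeg(
            mats,
            eeg.select_split("train"),
            eeg.select_split("validation"),
            eeg.select_split("test"),
        )
        nc = noise_ceiling(eeg.select_split("test"), n_reps=20, seed=4)
        ceiling_curve = nc.lower.mean(axis=0)
        # the split-half lower bound constrains models where stimulus signal
        # dominates; compare at each feature's accuracy peak (at low-SNR
        # timepoints a noise-free prediction can exceed a split-half r)
        for f, curve in acc.timecourses.items():
            peak = int(np.argmax(curve))
            assert curve[peak] <= ceiling_curve[peak] + 0.05, f

    def test_odd_repetitions_rejected(self, rng):
        from tests_helpers import toy_epochs

        epochs = toy_epochs(
            rng.standard_normal((9, 2, 3)), stimulus_ids=np.repeat(np.arange(3), 3)
        )
        with pytest.raises(ValueError):
            noise_ceiling(epochs)


def test_pearson_columns_matches_numpy(rng):
    A, B = rng.standard_normal((30, 4)), rng.standard_normal((30, 4))
    r = pearson_columns(A, B)
    expected = [np.corrcoef(A[:, j], B[:, j])[0, 1] for j in range(4)]
    assert np.allclose(r, expected)
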