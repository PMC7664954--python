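import numpy as np
import pytest

from imutrack.integration import integrate, remove_linear_drift
from imutrack.nn import LSTM, Dense, TrainingProtocol
from imutrack.nn.layers import sigmoid
from imutrack.regressors import (
    trial_axis_integration_pairs,
    IntegrativeWeightSpec,
    SequenceRegressor,
    StackedModel,
    assemble_warm_start_model,
    build_integrative_model,
    build_no_init_model,
    build_stacked_model,
    joint_loss,
    pretrain_single_integrator,
    segment_3d_displacement_pairs,
    segment_axis_displacement_pairs,
    segment_axis_integration_pairs,
    split_pairs_by_subject,
    train_displacement_regressor,
    train_stacked,
)

DT = 1.0 / 120.0


def euler_double(a, dt=DT):
    v = integrate(a, dt, 0.0)
    return integrate(v, dt, 0.0)


class TestIntegrativeModel:
    def test_zero_input_gives_zero_output(self):
        model = build_integrative_model(DT, seed=0)
        out = model.predict(np.zeros((240, 1)))
        assert np.max(np.abs(out)) < 1e-6

    def test_constant_acceleration_matches_euler(self):
        model = build_integrative_model(DT, seed=0)
        a = np.ones((240, 1))
        out = model.predict(a)
        expected = euler_double(a)
        rel = abs(out[-1, 0] - expected[-1, 0]) / abs(expected[-1, 0])
        assert rel < 1e-3

    def test_oracle_equivalence_on_100_random_series(self):
        model = build_integrative_model(DT, seed=0)
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(100):
            a = rng.standard_normal((240, 1)) * 2
            expected = euler_double(a)
            out = model.predict(a)
            scale = max(np.max(np.abs(expected)), 1e-12)
            worst = max(worst, np.max(np.abs(out - expected)) / scale)
        assert worst < 1e-3

    def test_gate_saturation_for_bounded_inputs(self):
        model = build_integrative_model(DT, seed=0)
        for lstm in model.blocks[:2]:
            H = lstm.hidden_size
            x = np.full(lstm.input_size, 10.0)
            z = x @ lstm.params["Wx"] + lstm.params["b"]
            gates = sigmoid(np.concatenate([z[:H], z[H : 2 * H], z[3 * H :]]))
            assert gates.min() >= 0.9999

    def test_symmetry_breaking_distinct_gate_weights(self):
        model = build_integrative_model(DT, seed=0)
        lstm = model.blocks[1]
        H = lstm.hidden_size
        gate_w = np.concatenate(
            [
                lstm.params["Wx"][:, :2 * H].ravel(),
                lstm.params["Wx"][:, 3 * H :].ravel(),
            ]
        )
        assert len(np.unique(gate_w)) == len(gate_w)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            IntegrativeWeightSpec(dt=0.0)
        with pytest.raises(ValueError):
            IntegrativeWeightSpec(dt=DT, gate_bias=2.0)  # sigmoid(2) < 0.9999


class TestNoInitModel:
    @pytest.mark.parametrize("channels", [3, 6, 9])
    def test_forward_shape(self, channels, rng):
        model = build_no_init_model(channels, seed=0)
        out = model.predict(rng.standard_normal((50, channels)))
        assert out.shape == (50, 3)

    def test_invalid_channel_count_rejected(self):
        with pytest.raises(ValueError):
            build_no_init_model(4)

    def test_training_halves_loss(self, segment_dataset):
        model = build_no_init_model(3, seed=0)
        tr, va = split_pairs_by_subject(
            segment_dataset, segment_3d_displacement_pairs, seed=0, input_channels=3
        )
        proto = TrainingProtocol(batch_size=1, max_epochs=15)
        hist = train_displacement_regressor(model, tr, va, proto, seed=0)
        assert hist["train_loss"][-1] <= 0.5 * hist["train_loss"][0]


@pytest.fixture(scope="module")
def pretrained(segment_dataset):
    pairs = trial_axis_integration_pairs(segment_dataset)
    proto = TrainingProtocol(batch_size=1, max_epochs=15)
    return pretrain_single_integrator(pairs, proto, seed=0)


class TestPretrainedWarmStart:

    def test_pretraining_beats_random_init(self, pretrained, segment_dataset):
        model, _ = pretrained
        rng = np.random.default_rng(123)
        random_model = SequenceRegressor([LSTM(1, 30, rng), Dense(30, 1, rng)])
        pairs = segment_axis_integration_pairs(segment_dataset)[:6]

        def rmse(m):
            return np.mean(
                [np.sqrt(np.mean((m.predict(x) - y) ** 2)) for x, y in pairs]
            )

        assert rmse(model) < rmse(random_model)

    def test_zero_input_near_zero_velocity(self, pretrained, segment_dataset):
        model, _ = pretrained
        targets = trial_axis_integration_pairs(segment_dataset)
        scale = max(np.abs(y).max() for _, y in targets)
        out = model.predict(np.zeros((100, 1)))
        assert np.abs(out).max() < 0.05 * scale

    def test_drift_targets_have_smaller_end_velocity(self, segment_dataset):
        plain = segment_axis_integration_pairs(segment_dataset, drift_corrected=False)
        drift = segment_axis_integration_pairs(segment_dataset, drift_corrected=True)
        assert len(plain) >= 10
        plain_end = np.mean([abs(y[-1, 0]) for _, y in plain])
        drift_end = np.mean([abs(y[-1, 0]) for _, y in drift])
        assert drift_end < plain_end

    def test_assembled_plain_variant_duplicates_layers(self, pretrained):
        model, _ = pretrained
        asm = assemble_warm_start_model(model, model)
        np.testing.assert_array_equal(
            asm.blocks[0].params["Wx"], asm.blocks[2].params["Wx"]
        )
        np.testing.assert_array_equal(
            asm.blocks[1].params["W"], asm.blocks[3].params["W"]
        )

    def test_assembled_drift_variant_layer_order(self, pretrained, segment_dataset):
        plain, _ = pretrained
        drift_pairs = segment_axis_integration_pairs(segment_dataset, drift_corrected=True)
        proto = TrainingProtocol(batch_size=1, max_epochs=3)
        drift, _ = pretrain_single_integrator(drift_pairs, proto, seed=1)
        asm = assemble_warm_start_model(drift, plain)
        np.testing.assert_array_equal(
            asm.blocks[0].params["Wx"], drift.blocks[0].params["Wx"]
        )
        np.testing.assert_array_equal(
            asm.blocks[2].params["Wx"], plain.blocks[0].params["Wx"]
        )

    def test_assembled_beats_random_against_euler_oracle(
        self, pretrained, segment_dataset
    ):
        model, _ = pretrained
        asm = assemble_warm_start_model(model, model)
        rng = np.random.default_rng(7)
        rand = SequenceRegressor(
            [LSTM(1, 30, rng), Dense(30, 1, rng), LSTM(1, 30, rng), Dense(30, 1, rng)]
        )
        mse_asm = mse_rand = 0.0
        for x, _ in segment_axis_integration_pairs(segment_dataset)[:8]:
            expected = euler_double(x)
            mse_asm += np.mean((asm.predict(x) - expected) ** 2)
            mse_rand += np.mean((rand.predict(x) - expected) ** 2)
        assert mse_asm < mse_rand

    def test_incompatible_shapes_rejected(self, pretrained):
        model, _ = pretrained
        with pytest.raises(ValueError):
            assemble_warm_start_model(model, build_no_init_model(3))


class TestTrainDisplacementRegressor:
    def test_targets_start_near_zero(self, segment_dataset):
        pairs = segment_axis_displacement_pairs(segment_dataset)
        for _, y in pairs:
            assert abs(y[0, 0]) < 1e-3

    def test_best_val_loss_non_increasing(self, segment_dataset):
        model = build_no_init_model(3, seed=0)
        tr, va = split_pairs_by_subject(
            segment_dataset, segment_3d_displacement_pairs, seed=0, input_channels=3
        )
        proto = TrainingProtocol(batch_size=1, max_epochs=8)
        hist = train_displacement_regressor(model, tr, va, proto, seed=0)
        best = np.minimum.accumulate(hist["val_loss"])
        assert np.all(np.diff(best) <= 1e-12)

    def test_variant_a_stays_at_euler_accuracy_on_clean_data(self):
        from imutrack.synthetic import ImuErrorSpec, TrajectorySpec, make_dataset

        clean = make_dataset(
            3,
            ["rsho"],
            1,
            TrajectorySpec(
                n_segments=7,
                dwell_duration_range=(0.3, 0.6),
                move_duration_range=(0.6, 1.2),
            ),
            ImuErrorSpec(),
            master_seed=11,
        )
        dt = clean[0][0].dt
        model = build_integrative_model(dt, seed=0)
        tr, va = split_pairs_by_subject(clean, segment_axis_displacement_pairs, seed=0)
        proto = TrainingProtocol(batch_size=1, max_epochs=3)
        train_displacement_regressor(model, tr, va, proto, seed=0)
        model_err, euler_err = [], []
        for x, y in va:
            model_err.append(abs(model.predict(x)[-1, 0] - y[-1, 0]))
            euler_err.append(abs(euler_double(x, dt)[-1, 0] - y[-1, 0]))
        assert np.mean(model_err) <= 2 * np.mean(euler_err)


class TestJointLoss:
    def test_alpha_one_is_pure_mse(self, rng):
        y_reg = rng.standard_normal((10, 3))
        yhat = rng.standard_normal((10, 3))
        y_cl = rng.integers(0, 2, 10).astype(float)
        p = rng.uniform(0.01, 0.99, 10)
        expected = np.mean((y_reg - yhat) ** 2)
        assert joint_loss(y_cl, p, y_reg, yhat, 1.0) == pytest.approx(
            expected, abs=1e-12
        )

    def test_alpha_zero_perfect_probabilities(self):
        y_cl = np.array([1.0, 0.0, 1.0])
        p = np.array([1.0, 0.0, 1.0])
        y = np.zeros((3, 3))
        loss = joint_loss(y_cl, p, y, np.ones((3, 3)), 0.0)
        assert loss == pytest.approx(0.0, abs=1e-5)

    def test_hand_computed_example(self):
        # N=1, alpha=0.5: 0.5*(-ln 0.5) + 0.5*(1/3) ~= 0.51324
        loss = joint_loss(
            np.array([1.0]),
            np.array([0.5]),
            np.zeros((1, 3)),
            np.array([[1.0, 0.0, 0.0]]),
            0.5,
        )
        assert loss == pytest.approx(0.51324, abs=5e-6)

    def test_linear_in_alpha(self, rng):
        y_cl = rng.integers(0, 2, 20).astype(float)
        p = rng.uniform(0.05, 0.95, 20)
        y_reg = rng.standard_normal((20, 3))
        yhat = rng.standard_normal((20, 3))
        l0 = joint_loss(y_cl, p, y_reg, yhat, 0.0)
        l1 = joint_loss(y_cl, p, y_reg, yhat, 1.0)
        for alpha in (0.25, 0.5, 0.8):
            expected = (1 - alpha) * l0 + alpha * l1
            assert joint_loss(y_cl, p, y_reg, yhat, alpha) == pytest.approx(
                expected, abs=1e-12
            )

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            joint_loss(np.array([1.0]), np.array([0.5]), np.zeros((1, 3)),
                       np.zeros((1, 3)), 1.5)

    def test_probabilities_clipped(self):
        loss = joint_loss(
            np.array([1.0]), np.array([0.0]), np.zeros((1, 3)), np.zeros((1, 3)), 0.0
        )
        assert np.isfinite(loss)


class TestStackedModel:
    def test_forward_shapes(self, rng):
        model = build_stacked_model(seed=0)
        p, y = model.forward(rng.standard_normal((1, 40, 6)))
        assert p.shape == (1, 40, 1)
        assert y.shape == (1, 40, 3)
        assert np.all((p > 0) & (p < 1))

    def test_small_run_label_accuracy(self):
        from imutrack.experiments import _train_stacked_for_config
        from imutrack.synthetic import ImuErrorSpec, TrajectorySpec, make_dataset

        spec = TrajectorySpec(
            n_segments=7,
            dwell_duration_range=(0.4, 0.8),
            move_duration_range=(0.6, 1.2),
        )
        err = ImuErrorSpec(
            accel_noise_sd=0.05, gyro_noise_sd=0.02, gyro_motion_scale=0.5
        )
        data = make_dataset(5, ["rsho"], 1, spec, err, master_seed=2)
        train, test = data[:4], data[4:]
        proto = TrainingProtocol(batch_size=1, max_epochs=25)
        model = _train_stacked_for_config(train, alpha=0.5, protocol=proto, seed=0)
        trial, _, labels = test[0]
        p, _ = model.predict_trial(trial)
        acc = np.mean((p >= 0.5).astype(int) == labels.labels)
        assert acc > 0.85

    def test_train_stacked_rejects_empty_validation(self, rng):
        model = build_stacked_model(seed=0)
        sample = (rng.standard_normal((20, 6)), np.ones(20), np.zeros((20, 3)))
        with pytest.raises(ValueError):
            train_stacked(model, [sample], [], alpha=0.5)
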