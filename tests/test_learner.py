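"""Online-learner tests: network contracts, loss, schedule, gradient
routing, termination, and parameter recovery on synthetic streams."""

import numpy as np
import pandas as pd
import pytest

from tumblefit.dynamics import EquationParams, OblateGeometry, PLATELET, flip_period
from tumblefit.learner import (
    BIOLRegressor,
    LearnerState,
    LossBreakdown,
    OptimizerConfig,
    TerminationConfig,
    biol_loss,
    check_termination,
    encode_angle,
    learning_rate,
    run_online_loop,
    train_process,
)
from tumblefit.network import SurrogateNet
from tumblefit.preprocess import preprocess_series
from tumblefit.sampler import SamplingPolicy, draw_training_batch
from tumblefit.synthetic import (
    RIGID_PARAMS,
    ScenarioSpec,
    default_rigid_scenario,
    generate_ground_truth,
)


def _make_state(seed=0):
    return LearnerState(net=SurrogateNet(seed=seed), params=EquationParams())


@pytest.fixture(scope="module")
def joe_batch():
    series = generate_ground_truth(ScenarioSpec(duration=10.0, seed=0))
    proc = preprocess_series(series.samples)
    return draw_training_batch(proc, 8.5, SamplingPolicy(), rng=0)


@pytest.fixture(scope="module")
def rigid_recovery():
    """Online loop on a noiseless rigid stream with known parameters."""
    truth = RIGID_PARAMS  # (0.5, -0.1, 0)
    period = flip_period(truth, PLATELET)
    scenario = default_rigid_scenario(
        duration=8.0 + period + 0.5, sample_interval=0.005, seed=2
    )
    series = generate_ground_truth(scenario)
    proc = preprocess_series(series.samples)
    state, trajectory = run_online_loop(proc, body_type="rigid", seed=0)
    return truth, state, trajectory


class TestNetwork:
    def test_zero_weights_give_zero_output(self):
        net = SurrogateNet(seed=0)
        net.weights = [np.zeros_like(w) for w in net.weights]
        net.biases = [np.zeros_like(b) for b in net.biases]
        out = net.forward(encode_angle(np.linspace(0, 3, 7)))
        np.testing.assert_array_equal(out, 0.0)

    def test_init_seed_reproducible(self):
        x = encode_angle(np.linspace(0, 3, 11))
        a, b = SurrogateNet(seed=5), SurrogateNet(seed=5)
        np.testing.assert_array_equal(a.forward(x), b.forward(x))
        c = SurrogateNet(seed=6)
        assert not np.array_equal(a.forward(x), c.forward(x))

    def test_lipschitz_bound(self):
        """tanh layers are 1-Lipschitz, so a delta-perturbation of one
        input moves the output by at most prod(||W||_2) * delta."""
        net = SurrogateNet(seed=1)
        bound = np.prod([np.linalg.norm(w, 2) for w in net.weights])
        x = encode_angle([0.7])
        delta = 1e-3
        x2 = x.copy()
        x2[0, 0] += delta
        change = abs(net.forward(x2)[0] - net.forward(x)[0])
        assert change <= bound * delta + 1e-12

    def test_backward_matches_finite_differences(self):
        net = SurrogateNet(seed=3, hidden_layers=2, width=5)
        x = encode_angle(np.array([0.3, 1.1, -0.4]))
        d_out = np.array([1.0, -2.0, 0.5])
        w_grads, b_grads = net.backward(x, d_out)
        h = 1e-6
        w = net.weights[1]
        for idx in [(0, 0), (2, 3)]:
            w[idx] += h
            up = float(d_out @ net.forward(x))
            w[idx] -= 2 * h
            dn = float(d_out @ net.forward(x))
            w[idx] += h
            assert w_grads[1][idx] == pytest.approx((up - dn) / (2 * h),
                                                    rel=1e-5, abs=1e-9)


class TestLossAndSchedule:
    def test_all_equal_zero_loss(self):
        v = np.ones(5)
        loss = biol_loss(v, v, v)
        assert (loss.l1, loss.l2, loss.total, loss.l3) == (0, 0, 0, 0)

    def test_direct_mse(self):
        loss = biol_loss([1.0, 1.0], [0.9, 1.1], [1.0, 1.0])
        assert loss.l1 == pytest.approx(0.01)
        assert loss.l2 == pytest.approx(0.01)
        assert loss.total == pytest.approx(0.02)

    def test_permutation_invariance(self):
        gt, ml, th = [1.0, 2.0, 3.0], [1.1, 1.9, 3.2], [0.9, 2.1, 2.8]
        a = biol_loss(gt, ml, th)
        b = biol_loss(gt[::-1], ml[::-1], th[::-1])
        assert a.total == pytest.approx(b.total)

    def test_rejects_mismatched_lengths(self):
        with pytest.raises(ValueError):
            biol_loss([1.0], [1.0, 2.0], [1.0])

    @pytest.mark.parametrize(
        "k, expected", [(0, 0.002), (1, 0.0019), (200, 0.0005)]
    )
    def test_learning_rate_schedule(self, k, expected):
        assert learning_rate(k, OptimizerConfig()) == pytest.approx(expected)

    def test_epoch_counts_by_body_type(self):
        cfg = OptimizerConfig()
        assert cfg.epochs("rigid") == 200
        assert cfg.epochs("deformable") == 300


class TestTrainProcess:
    def test_params_stay_near_zero_on_joe_data(self, joe_batch):
        state = train_process(
            _make_state(0), joe_batch, PLATELET, OptimizerConfig()
        )
        assert abs(state.params.kappa0) < 0.05
        assert abs(state.params.lambda0) < 0.05
        assert abs(state.params.lambda1) < 0.05

    def test_loss_decreases_over_process(self, joe_batch):
        state = _make_state(1)
        frame = pd.concat(joe_batch.series_list, ignore_index=True)
        x = encode_angle(frame["phi_f"].to_numpy())
        gt = frame["phi_dot"].to_numpy()
        first = float(np.mean((gt - state.net.forward(x)) ** 2))
        state = train_process(state, joe_batch, PLATELET, OptimizerConfig())
        assert state.loss_history[-1].total <= first

    def test_epoch_count_rigid_vs_deformable(self, joe_batch):
        for body, expected in (("rigid", 200), ("deformable", 300)):
            state = train_process(
                _make_state(2), joe_batch, PLATELET, OptimizerConfig(),
                body_type=body,
            )
            assert state.step_count == expected

    def test_gradient_routing(self, joe_batch):
        """L1 never moves the equation parameters; L2 never moves the
        network weights (checked by zeroing each loss in turn)."""
        # L2 == 0: params match net output exactly is impossible, so
        # instead freeze the routing by checking param update uses only
        # (th - ml): a net trained with gt == its own output leaves L1 at
        # zero and must not change weights.
        state = _make_state(3)
        frame = pd.concat(joe_batch.series_list[:2], ignore_index=True)
        x = encode_angle(frame["phi_f"].to_numpy())
        ml = state.net.forward(x)
        synthetic = frame.copy()
        synthetic["phi_dot"] = ml  # gt equals the net's own prediction
        batch = type(joe_batch)(
            series_list=[synthetic], region_labels=np.array([0]),
            draw_time=joe_batch.draw_time,
        )
        w_before = [w.copy() for w in state.net.weights]
        cfg = OptimizerConfig(epochs_rigid=1)
        state = train_process(state, batch, PLATELET, cfg)
        for w0, w1 in zip(w_before, state.net.weights):
            np.testing.assert_array_equal(w0, w1)
        # and the parameters did move (L2 > 0 here)
        assert any(
            abs(v) > 0 for v in (state.params.kappa0, state.params.lambda0)
        )

    def test_checkpoint_round_trip_bitwise(self, joe_batch):
        state = train_process(
            _make_state(4), joe_batch, PLATELET,
            OptimizerConfig(epochs_rigid=3),
        )
        text = state.to_checkpoint()
        back = LearnerState.from_checkpoint(text)
        assert back.to_checkpoint() == text
        for w0, w1 in zip(state.net.weights, back.net.weights):
            np.testing.assert_array_equal(w0, w1)
        assert back.params == state.params


class TestTermination:
    def test_empty_history_not_triggered(self):
        assert not check_termination(_make_state()).triggered

    def test_all_zero_losses_trigger(self):
        state = _make_state()
        state.loss_history = [LossBreakdown(0.0, 0.0)] * 10
        assert check_termination(state).triggered

    def test_high_variance_blocks(self):
        cfg = TerminationConfig(lookback=10, mean_threshold=1e6,
                                sd_threshold=1e-3)
        state = _make_state()
        state.loss_history = [
            LossBreakdown(0.0, 0.0) if i % 2 else LossBreakdown(0.01, 0.0)
            for i in range(10)
        ]
        assert not check_termination(state, cfg).triggered


class TestOnlineLoop:
    def test_recovers_rigid_parameters(self, rigid_recovery):
        truth, state, _ = rigid_recovery
        assert state.params.kappa0 == pytest.approx(truth.kappa0, abs=0.1)
        assert state.params.lambda0 == pytest.approx(truth.lambda0, abs=0.1)
        assert state.params.lambda1 == pytest.approx(truth.lambda1, abs=0.1)

    def test_two_stage_loss_pattern(self, rigid_recovery):
        """The evaluation loss drops steeply within the first flip period
        and stays low afterwards."""
        _, _, traj = rigid_recovery
        l3 = traj["l3"].to_numpy()
        early, late = l3[: len(l3) // 3], l3[2 * len(l3) // 3:]
        assert np.min(early) < 0.1 * l3[0]
        assert np.max(late) < 0.1 * l3[0]

    def test_master_seed_determinism(self):
        scenario = default_rigid_scenario(duration=9.5, seed=3)
        proc = preprocess_series(generate_ground_truth(scenario).samples)
        opt = dict(
            optimizer=OptimizerConfig(epochs_rigid=20), stride=0.5, seed=9
        )
        _, a = run_online_loop(proc, **opt)
        _, b = run_online_loop(proc, **opt)
        pd.testing.assert_frame_equal(a, b)

    def test_short_stream_warns_and_returns_empty(self):
        proc = preprocess_series(
            generate_ground_truth(ScenarioSpec(duration=3.0, seed=0)).samples
        )
        with pytest.warns(UserWarning, match="shorter than the window"):
            state, traj = run_online_loop(proc)
        assert len(traj) == 0


class TestEstimatorInterface:
    def test_sklearn_contract(self):
        from sklearn.base import clone

        est = BIOLRegressor(stride=0.5, epochs_rigid=10)
        params = est.get_params()
        assert params["stride"] == 0.5
        clone(est)  # must not raise
        est.set_params(stride=0.25)
        assert est.stride == 0.25

    def test_fit_predict_on_array_input(self):
        scenario = default_rigid_scenario(duration=9.5, seed=3)
        proc = preprocess_series(generate_ground_truth(scenario).samples)
        X = proc[["gamma_t", "phi_f", "phi_dot"]].to_numpy()
        est = BIOLRegressor(
            stride=0.5, epochs_rigid=20, body_type="rigid", random_state=0
        )
        est.fit(X)
        assert hasattr(est, "params_")
        speeds = est.predict(np.linspace(0, np.pi, 9))
        assert speeds.shape == (9,)
        assert np.all(np.isfinite(speeds))

    def test_predict_before_fit_raises(self):
        with pytest.raises(RuntimeError):
            BIOLRegressor().predict([0.1])
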