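"""Gradients, optimizers and measurement-budget accounting."""

import math

import numpy as np
import pytest

import qclreg as q
from qclreg.simulator import Gate, StateVector
from qclreg.circuits import ParameterizedCircuit
from qclreg.training import (
    EXACT,
    AdamState,
    EncodedDataset,
    LossSpec,
    ShotBudget,
    adam_step,
    mse_loss,
    shots_per_step,
    train_nelder_mead,
    train_sgd,
)


def one_qubit_ry_circuit() -> ParameterizedCircuit:
    return ParameterizedCircuit(
        n_qubits=1,
        gates=(Gate("RY", 0, angles=(0.0,), trainable=(True,)),),
        trainable_slots=((0, 0),),
        readout_qubit=0,
    )


class TestShotAccounting:
    def test_nelder_mead_budget_is_shots_times_samples(self):
        budget = ShotBudget(10_000, 86, 24)
        assert shots_per_step(budget, "nelder_mead") == 860_000

    def test_sgd_budget_counts_forward_plus_two_shifts_per_parameter(self):
        budget = ShotBudget(100, 86, 24)
        assert shots_per_step(budget, "sgd_param_shift") == 4_900

    def test_minimal_budget(self):
        assert shots_per_step(ShotBudget(1, 1, 1), "nelder_mead") == 1


class TestParameterShift:
    @pytest.mark.parametrize(
        "theta, expected",
        [(0.0, 0.0), (math.pi / 2, -1.0), (math.pi / 3, -math.sin(math.pi / 3))],
    )
    def test_matches_closed_form_minus_sine(self, theta, expected):
        """B(theta) = cos(theta) for RY(theta)|0>, so dB/dtheta = -sin(theta)."""
        circ = one_qubit_ry_circuit()
        grad = q.parameter_shift_gradient(
            np.array([theta]), circ, StateVector.zero(1)
        )
        assert grad[0] == pytest.approx(expected, abs=1e-12)

    def test_finite_difference_closed_form(self):
        circ = one_qubit_ry_circuit()
        grad = q.finite_difference_gradient(
            np.array([math.pi / 3]), circ, StateVector.zero(1), h=1e-6
        )
        assert grad[0] == pytest.approx(-0.8660, abs=1e-4)

    def test_agrees_with_finite_difference_on_mera(self, mera, rng):
        x = rng.uniform(-math.pi, math.pi, 4)
        state = q.encode_state(x)
        for _ in range(5):
            theta = rng.uniform(0, 2 * math.pi, 24)
            ps = q.parameter_shift_gradient(theta, mera, state)
            fd = q.finite_difference_gradient(theta, mera, state, h=1e-6)
            assert np.max(np.abs(ps - fd)) < 1e-4

    def test_zero_h_rejected(self, mera, rng):
        with pytest.raises(ValueError):
            q.finite_difference_gradient(
                np.zeros(24), mera, StateVector.zero(4), h=0.0
            )


class TestMseLoss:
    def test_perfect_predictions_give_zero(self, mera):
        theta = np.zeros(24)  # identity ansatz on |0000> -> B = +1 everywhere
        enc = EncodedDataset(np.zeros((3, 4)), np.ones(3))
        assert mse_loss(theta, enc, mera) == pytest.approx(0.0)

    def test_single_sample_squared_error(self, mera):
        enc = EncodedDataset(np.zeros((1, 4)), np.array([0.5]))
        # zero theta predicts +1; (0.5 - 1)^2 = 0.25
        assert mse_loss(np.zeros(24), enc, mera) == pytest.approx(0.25)

    def test_full_batch_is_mean_of_per_sample_losses(self, mera, rng):
        X = rng.uniform(-math.pi, math.pi, (5, 4))
        y = rng.uniform(-0.7, 0.7, 5)
        enc = EncodedDataset(X, y)
        theta = rng.uniform(0, 2 * math.pi, 24)
        per_sample = [
            (y[i] - q.ansatz_expectation(enc.states[i], mera, theta)) ** 2
            for i in range(5)
        ]
        assert mse_loss(theta, enc, mera) == pytest.approx(np.mean(per_sample))

    def test_sampled_loss_converges_to_exact(self, mera, encoded_default, rng):
        theta = rng.uniform(0, 2 * math.pi, 24)
        exact = mse_loss(theta, encoded_default, mera)
        sampled = mse_loss(
            theta, encoded_default, mera, LossSpec(shots=10**6), rng
        )
        assert abs(sampled - exact) < 1e-2


class TestAdam:
    def test_zero_gradient_leaves_theta_unchanged(self):
        theta = np.array([1.0, -2.0])
        new, _ = adam_step(theta, np.zeros(2), AdamState.zeros(2))
        np.testing.assert_allclose(new, theta)

    def test_constant_gradient_step_magnitude_approaches_lr(self):
        """With a constant gradient, Adam's normalized step tends to lr."""
        theta = np.zeros(1)
        state = AdamState.zeros(1)
        g = np.array([0.37])
        for _ in range(200):
            new, state = adam_step(theta, g, state, lr=0.03)
            step = new - theta
            theta = new
        assert abs(abs(step[0]) - 0.03) < 1e-3

    def test_nonfinite_gradient_aborts(self):
        with pytest.raises(FloatingPointError):
            adam_step(np.zeros(1), np.array([np.nan]), AdamState.zeros(1))


class TestTrainSgd:
    def test_trace_length_and_cumulative_shots(self, mera, encoded_default):
        _, trace = train_sgd(
            encoded_default, mera, shots=100, n_steps=12, seed=0, eval_r2_every=6
        )
        assert len(trace) == 12
        assert trace.cum_shots == [4_900 * (s + 1) for s in range(12)]

    def test_exact_run_records_zero_shots(self, mera, encoded_default):
        _, trace = train_sgd(
            encoded_default, mera, shots=EXACT, n_steps=3, seed=0
        )
        assert trace.cum_shots == [0, 0, 0]

    def test_deterministic_under_seed(self, mera, encoded_default):
        t1, tr1 = train_sgd(encoded_default, mera, shots=100, n_steps=8, seed=5,
                            eval_r2_every=8)
        t2, tr2 = train_sgd(encoded_default, mera, shots=100, n_steps=8, seed=5,
                            eval_r2_every=8)
        np.testing.assert_array_equal(t1, t2)
        assert tr1.losses == tr2.losses

    def test_exact_training_improves_r2_over_initialization(
        self, mera, encoded_default
    ):
        theta, trace = train_sgd(
            encoded_default, mera, shots=EXACT, n_steps=300, seed=1,
            eval_r2_every=50,
        )
        assert trace.r2s[-1] > 0.0
        assert trace.r2s[-1] > trace.r2s[0]

    def test_invalid_steps_rejected(self, mera, encoded_default):
        with pytest.raises(ValueError):
            train_sgd(encoded_default, mera, n_steps=0)


class TestTrainNelderMead:
    def test_best_so_far_loss_is_monotone_on_exact_objective(
        self, mera, encoded_default
    ):
        _, trace = train_nelder_mead(
            encoded_default, mera, shots=EXACT, max_fev=60, seed=0,
            eval_r2_every=30,
        )
        best = np.minimum.accumulate(trace.losses)
        assert np.all(np.diff(best) <= 0)
        assert trace.losses[np.argmin(trace.losses)] <= trace.losses[0]

    def test_shot_accounting_at_ten_thousand_shots(self, mera, encoded_default):
        _, trace = train_nelder_mead(
            encoded_default, mera, shots=10_000, max_fev=3, seed=0,
            eval_r2_every=3,
        )
        assert trace.cum_shots[0] == 860_000  # 10,000 x 86 samples
        assert trace.cum_shots[1] == 2 * 860_000

    def test_invalid_max_fev_rejected(self, mera, encoded_default):
        with pytest.raises(ValueError):
            train_nelder_mead(encoded_default, mera, max_fev=0)


def test_predict_one_identity_circuit_returns_plus_one(mera):
    value = q.predict_one(np.zeros(4), np.zeros(24), mera)
    assert value == pytest.approx(1.0)


def test_predict_one_bounded_and_seed_deterministic(mera, rng):
    x = rng.uniform(-math.pi, math.pi, 4)
    theta = rng.uniform(0, 2 * math.pi, 24)
    assert -1.0 <= q.predict_one(x, theta, mera) <= 1.0
    a = q.predict_one(x, theta, mera, shots=100, rng=np.random.default_rng(11))
    b = q.predict_one(x, theta, mera, shots=100, rng=np.random.default_rng(11))
    assert a == b
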