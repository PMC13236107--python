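"""Variational learner: ansatz structure, loss, gradients, training."""

import numpy as np
import pytest
from dataclasses import replace

from qensemble import backend
from qensemble.varqc import (
    HYPERPARAMETER_GRID,
    TrainingConfig,
    VariationalLearner,
    bce_loss,
    build_ansatz,
    grid_search,
    n_parameters,
    parameter_shift_gradient,
    predict_proba,
    random_learner,
    readout_probability,
    train_learner,
)


class TestAnsatzStructure:
    @pytest.mark.parametrize("n_features, n_qubits, n_params",
                             [(2, 1, 6), (4, 2, 12), (8, 3, 18)])
    def test_parameter_count_law(self, n_features, n_qubits, n_params):
        assert n_parameters(n_qubits) == n_params
        circ, state = build_ansatz(np.ones(n_features), np.zeros(n_params))
        assert circ.n_qubits == n_qubits
        assert state.n_qubits == n_qubits

    def test_single_qubit_has_no_cnots(self):
        circ, _ = build_ansatz([1.0, 0.5], np.zeros(6))
        assert all(len(op.control_qubits) == 0 for op in circ.ops)

    def test_cnot_chain_is_linear(self):
        circ, _ = build_ansatz(np.ones(8), np.zeros(18))
        cnots = [op for op in circ.ops if op.control_qubits]
        assert [(op.control_qubits[0], op.target_qubits[0]) for op in cnots] == [
            (0, 1), (1, 2)
        ]

    def test_zero_theta_rotations_are_identity(self, rng):
        # one qubit: no CNOT layer, so zero angles leave the encoding untouched
        x = rng.random(2) + 0.01
        circ, state = build_ansatz(x, np.zeros(6))
        out = circ.run(state)
        np.testing.assert_allclose(out.amplitudes, state.amplitudes, atol=1e-10)
        # two qubits: only the CNOT chain remains, a basis permutation
        x = rng.random(4) + 0.01
        circ, state = build_ansatz(x, np.zeros(12))
        out = circ.run(state)
        np.testing.assert_allclose(
            np.sort(np.abs(out.amplitudes)), np.sort(np.abs(state.amplitudes)),
            atol=1e-10,
        )

    def test_wrong_theta_length_rejected(self):
        with pytest.raises(ValueError):
            build_ansatz([1.0, 0.5], np.zeros(7))
        with pytest.raises(ValueError):
            VariationalLearner(2, np.zeros(6))


class TestReadout:
    def test_basis_zero_input(self):
        circ, state = build_ansatz([1.0, 0.0], np.zeros(6))
        assert readout_probability(circ, state) == pytest.approx((1.0, 0.0))

    def test_uniform_input(self):
        circ, state = build_ansatz([1.0, 1.0], np.zeros(6))
        p0, p1 = readout_probability(circ, state)
        assert p0 == pytest.approx(0.5)
        assert p1 == pytest.approx(0.5)

    def test_probabilities_sum_to_one(self, rng):
        for _ in range(10):
            lrn = random_learner(2, rng, scale=1.0)
            circ, state = build_ansatz(rng.random(4) + 0.01, lrn.theta)
            p0, p1 = readout_probability(circ, state)
            assert abs(p0 + p1 - 1.0) < 1e-10


class TestBCELoss:
    def test_perfect_predictions(self):
        assert bce_loss(np.array([1.0, 0.0]), np.array([1, 0])) < 1e-10

    def test_uninformative_predictions(self):
        assert bce_loss(np.full(4, 0.5), np.array([1, 0, 1, 0])) == pytest.approx(
            np.log(2)
        )

    def test_worked_example(self):
        expected = -(np.log(0.9) + np.log(0.8)) / 2
        assert bce_loss(np.array([0.9, 0.2]), np.array([1, 0])) == pytest.approx(
            expected
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bce_loss(np.array([0.5]), np.array([1, 0]))


class TestParameterShift:
    def test_matches_finite_differences(self, rng):
        """Analytic parameter-shift loss gradient agrees with central finite
        differences (step 1e-4) within 1e-5 on random learners."""
        for trial in range(20):
            n_qubits = int(rng.choice([1, 2]))
            lrn = random_learner(n_qubits, rng, scale=0.9)
            X = rng.random((2, 2**n_qubits)) + 0.05
            y = rng.integers(0, 2, 2)
            grad = parameter_shift_gradient(lrn, X, y)
            assert grad.shape == (n_parameters(n_qubits),)

            def loss(theta):
                p = np.array([predict_proba(replace(lrn, theta=theta), xi) for xi in X])
                return bce_loss(p, y.astype(float))

            h = 1e-4
            for j in range(grad.size):
                tp, tm = lrn.theta.copy(), lrn.theta.copy()
                tp[j] += h
                tm[j] -= h
                fd = (loss(tp) - loss(tm)) / (2 * h)
                assert abs(grad[j] - fd) < 1e-5

    def test_flat_parameter_has_zero_gradient(self):
        # with theta=0 and input |0>, p(1)=f(RY angles only): RZ entries flat
        lrn = VariationalLearner(1, np.zeros(6))
        grad = parameter_shift_gradient(lrn, np.array([[1.0, 0.0]]), np.array([1]))
        # RZ parameters (indices 0, 2, 3, 5) do not move the qubit-0 population
        assert abs(grad[0]) < 1e-12 and abs(grad[2]) < 1e-12


class TestTraining:
    def test_seeded_determinism(self, separable_blobs):
        X, y = separable_blobs.X[:16], separable_blobs.y[:16]
        cfg = TrainingConfig(learning_rate=1e-1, batch_size=4, epochs=3, seed=5)
        lrn = random_learner(1, 5)
        t1, trace1 = train_learner(lrn, X, y, cfg)
        t2, trace2 = train_learner(lrn, X, y, cfg)
        np.testing.assert_array_equal(t1.theta, t2.theta)
        assert trace1 == trace2

    def test_loss_decreases_on_separable_data(self, separable_blobs):
        X, y = separable_blobs.X, separable_blobs.y
        cfg = TrainingConfig(learning_rate=1e-1, batch_size=4, epochs=10, seed=3)
        trained, trace = train_learner(random_learner(1, 3), X, y, cfg)
        assert trace[-1] < trace[0]
        preds = np.array([1 if predict_proba(trained, xi) >= 0.5 else 0 for xi in X])
        assert (preds == y).mean() > 0.7

    def test_empty_data_rejected(self):
        cfg = TrainingConfig()
        with pytest.raises(ValueError):
            train_learner(random_learner(1, 0), np.empty((0, 2)), np.empty(0), cfg)


class TestGridSearch:
    def test_full_grid_cardinality(self):
        from itertools import product

        n = len(list(product(*HYPERPARAMETER_GRID.values())))
        assert n == 3 * 5 * 7 == 105

    def test_single_config_grid(self, separable_blobs):
        X, y = separable_blobs.X[:24], separable_blobs.y[:24]
        results = grid_search(
            X, y,
            grid={"learning_rate": [1e-1], "batch_size": [8], "ensemble_size": [1]},
            epochs=2, cv_folds=4, seed=0,
        )
        assert len(results) == 1
        assert 0.0 <= results[0]["median_val_accuracy"] <= 1.0
        assert len(results[0]["fold_accuracies"]) == 4

    def test_too_many_folds_rejected(self, separable_blobs):
        with pytest.raises(ValueError):
            grid_search(separable_blobs.X[:3], separable_blobs.y[:3],
                        grid={"learning_rate": [1e-1], "batch_size": [1],
                              "ensemble_size": [1]},
                        cv_folds=5)
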