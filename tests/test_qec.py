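"""Ensemble cosine classifier: width law, trajectory oracle, degeneracies."""

import numpy as np
import pytest

from qensemble.backend import ResourceError
from qensemble.qcc import QCCInstance, predict_qcc
from qensemble.qec import (
    QEC_GRID,
    QECRU_GRID,
    QECConfig,
    TrajectorySet,
    draw_trajectories,
    enumerate_trajectories,
    grid_widths,
    predict_qec,
    predict_qecru,
    qec_width,
    sample_slot_pairs,
    swap_transformation_matrix,
)


class TestWidthLaw:
    @pytest.mark.parametrize(
        "d, n_train, n_feature, width",
        [
            (1, 2, 2, 7),     # smallest hardware configuration
            (2, 8, 32, 56),   # largest hardware configuration
            (2, 8, 16, 47),   # validation-cohort hardware configuration
            (3, 4, 8, 23),    # random-unitary grid maximum
        ],
    )
    def test_reported_configurations(self, d, n_train, n_feature, width):
        assert qec_width(QECConfig(d=d, n_train=n_train, n_feature=n_feature)) == width

    def test_grid_extrema(self):
        assert min(grid_widths(QEC_GRID)) == 7
        assert max(grid_widths(QECRU_GRID, "haar")) == 23

    def test_qec_grid_enumeration(self):
        widths = grid_widths(QEC_GRID)
        assert len(widths) == 3 * 3 * 3 * 3
        # the widest *simulated* grid config (8 samples, 8 features, d=3);
        # the 56-qubit setting uses 32 features and lives off this grid
        assert max(widths) == 39

    def test_non_power_of_two_features_padded(self):
        assert qec_width(QECConfig(d=1, n_train=2, n_feature=3)) == qec_width(
            QECConfig(d=1, n_train=2, n_feature=4)
        )


class TestSwapTransformations:
    def test_two_slots_single_swap_is_transposition(self, rng):
        cfg = QECConfig(d=1, n_train=2, n_feature=2, n_swap=1)
        pairs = sample_slot_pairs(cfg, rng)
        assert len(pairs) == 1
        assert sorted(pairs[0]) == [0, 1]  # only one pair exists

    def test_double_swap_on_same_pair_is_identity(self):
        cfg = QECConfig(d=1, n_train=2, n_feature=2, n_swap=2)
        op = swap_transformation_matrix(cfg, [(0, 1), (0, 1)])
        np.testing.assert_allclose(op.matrix, np.eye(op.matrix.shape[0]))

    def test_matrix_is_permutation(self, rng):
        cfg = QECConfig(d=1, n_train=3, n_feature=2, n_swap=3)
        op = swap_transformation_matrix(cfg, sample_slot_pairs(cfg, rng))
        mat = op.matrix.real
        assert np.all((mat == 0) | (mat == 1))
        assert np.all(mat.sum(axis=0) == 1) and np.all(mat.sum(axis=1) == 1)

    def test_single_sample_has_no_pairs(self, rng):
        cfg = QECConfig(d=1, n_train=1, n_feature=2)
        with pytest.raises(ValueError):
            sample_slot_pairs(cfg, rng)


def _random_problem(rng, n_train, n_feature):
    X = rng.random((n_train, n_feature)) + 0.01
    y = rng.integers(0, 2, n_train)
    x_test = rng.random(n_feature) + 0.01
    return X, y, x_test


class TestTrajectoryOracle:
    def test_superposition_average_swap_variant(self, rng):
        """Statevector ensemble output = mean of the 2^d branch probabilities."""
        checked = 0
        while checked < 35:
            cfg = QECConfig(
                d=int(rng.integers(1, 4)),
                n_train=int(rng.choice([2, 4])),
                n_feature=int(rng.choice([2, 4])),
                n_swap=int(rng.choice([1, 2, 4])),
                seed=int(rng.integers(2**31 - 1)),
            )
            if qec_width(cfg) > 16:
                continue
            X, y, x_test = _random_problem(rng, cfg.n_train, cfg.n_feature)
            traj = draw_trajectories(cfg)
            p = predict_qec(cfg, X, y, x_test, traj)
            branches = enumerate_trajectories(cfg, X, y, x_test, traj)
            assert branches.shape == (2**cfg.d,)
            assert np.all((branches >= 0) & (branches <= 1))
            assert abs(p - branches.mean()) < 1e-8
            checked += 1

    def test_superposition_average_haar_variant(self, rng):
        for _ in range(15):
            cfg = QECConfig(
                d=int(rng.integers(1, 4)), n_train=2, n_feature=2,
                variant="haar", seed=int(rng.integers(2**31 - 1)),
            )
            X, y, x_test = _random_problem(rng, 2, 2)
            traj = draw_trajectories(cfg)
            p = predict_qecru(cfg, X, y, x_test, traj)
            branches = enumerate_trajectories(cfg, X, y, x_test, traj)
            assert 0.0 <= p <= 1.0
            assert abs(p - branches.mean()) < 1e-8

    def test_branch_counts(self, rng):
        for d in (1, 3):
            cfg = QECConfig(d=d, n_train=2, n_feature=2, seed=11)
            X, y, x_test = _random_problem(rng, 2, 2)
            traj = draw_trajectories(cfg)
            assert enumerate_trajectories(cfg, X, y, x_test, traj).size == 2**d


class TestDegenerateEnsembles:
    def test_identity_transformations_reduce_to_qcc(self, rng):
        """With no-op transformations the ensemble equals a plain weak learner
        on the slot-0 sample."""
        cfg = QECConfig(d=1, n_train=2, n_feature=2, seed=0)
        X, y, x_test = _random_problem(rng, 2, 2)
        identity = TrajectorySet("swap", (((), ()),))  # zero swaps each
        p_ens = predict_qec(cfg, X, y, x_test, identity)
        p_qcc = predict_qcc(QCCInstance(X[0], int(y[0]), x_test))
        assert p_ens == pytest.approx(p_qcc, abs=1e-10)

    def test_duplicated_training_samples_collapse(self, rng):
        cfg = QECConfig(d=2, n_train=2, n_feature=2, seed=4)
        x = rng.random(2) + 0.01
        X = np.vstack([x, x])
        y = np.array([1, 1])
        x_test = rng.random(2) + 0.01
        p_ens = predict_qec(cfg, X, y, x_test)
        p_qcc = predict_qcc(QCCInstance(x, 1, x_test))
        assert p_ens == pytest.approx(p_qcc, abs=1e-10)

    def test_perfect_match_gives_certainty(self):
        cfg = QECConfig(d=1, n_train=2, n_feature=2, seed=9)
        x = np.array([0.6, 0.8])
        p = predict_qec(cfg, np.vstack([x, x]), np.array([1, 1]), x)
        assert p == pytest.approx(1.0, abs=1e-10)


class TestResourceGuards:
    def test_wide_circuit_rejected_before_allocation(self):
        cfg = QECConfig(d=2, n_train=8, n_feature=32, seed=0)  # 56 qubits
        X = np.random.default_rng(0).random((8, 32)) + 0.01
        y = np.zeros(8, dtype=int)
        with pytest.raises(ResourceError):
            predict_qec(cfg, X, y, X[0], TrajectorySet("swap", (((0, 1),), ((0, 1),))))

    def test_haar_support_cap(self):
        with pytest.raises(ResourceError):
            QECConfig(d=1, n_train=8, n_feature=8, variant="haar")

    def test_seeded_reproducibility(self, rng):
        cfg = QECConfig(d=2, n_train=2, n_feature=2, variant="haar", seed=77)
        X, y, x_test = _random_problem(rng, 2, 2)
        assert predict_qec(cfg, X, y, x_test) == predict_qec(cfg, X, y, x_test)
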