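"""Variational weak learner: amplitude embedding, RZ-RY-RZ layers, CNOT chain.

Each learner amplitude-encodes an f-dimensional feature vector into
n = log2(f_padded) qubits, applies a trainable RZ-RY-RZ rotation to every
qubit, a linear CNOT chain (i -> i+1, only when n > 1), a second rotation
layer, and reads class probabilities off qubit 0 — 6n trainable parameters
in total. Training is mini-batch gradient descent with Adam on binary cross
entropy, with analytic parameter-shift gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import Sequence

import numpy as np

from . import backend
from .backend import StateVector, amplitude_encode
from .circuit import Circuit

EPS_CLIP = 1e-12


def n_qubits_for_features(n_features: int) -> int:
    return max(1, int(np.ceil(np.log2(n_features))))


def n_parameters(n_qubits: int) -> int:
    """Trainable parameter count: 2 rotation layers x 3 angles per qubit."""
    return 6 * n_qubits


@dataclass(frozen=True)
class VariationalLearner:
    """An ansatz parameter vector theta (length 6n) plus its register size."""

    n_qubits: int
    theta: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        th = np.asarray(self.theta, dtype=float)
        object.__setattr__(self, "theta", th)
        if th.shape != (n_parameters(self.n_qubits),):
            raise ValueError(
                f"theta must have length {n_parameters(self.n_qubits)} "
                f"for {self.n_qubits} qubits, got {th.shape}"
            )


def random_learner(n_qubits: int, rng: np.random.Generator | int | None = None,
                   scale: float = 0.1) -> VariationalLearner:
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    theta = rng.normal(0.0, scale, size=n_parameters(n_qubits))
    return VariationalLearner(n_qubits, theta)


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the variational training loop."""

    learning_rate: float = 1e-2
    batch_size: int = 4
    ensemble_size: int = 1
    epochs: int = 30
    cv_folds: int = 4
    seed: int | None = None
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("learning_rate, batch_size, epochs must be positive")
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cross-validation needs at least 2 folds")


#: the hyperparameter grid explored for the variational ensembles
HYPERPARAMETER_GRID = {
    "learning_rate": (1e-3, 1e-2, 1e-1),
    "batch_size": (1, 2, 4, 8, 16),
    "ensemble_size": (1, 2, 3, 4, 5, 6, 7),
}


def build_ansatz(x: Sequence[float], theta: np.ndarray) -> tuple[Circuit, StateVector]:
    """Assemble the parameterized circuit for one sample.

    Parameter layout: theta[3q : 3q+3] are the first-layer (RZ, RY, RZ)
    angles of qubit q; the second layer starts at offset 3n.
    """
    state = amplitude_encode(x)
    n = state.n_qubits
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (n_parameters(n),):
        raise ValueError(f"theta must have length {n_parameters(n)} for {n} qubits")
    circ = Circuit(n)

    def rotation_layer(offset: int) -> None:
        for q in range(n):
            a, b, c = theta[offset + 3 * q : offset + 3 * q + 3]
            circ.unitary(backend.rz(a), [q])
            circ.unitary(backend.ry(b), [q])
            circ.unitary(backend.rz(c), [q])

    rotation_layer(0)
    if n > 1:
        for q in range(n - 1):
            circ.cnot(q, q + 1)
    rotation_layer(3 * n)
    return circ, state


def readout_probability(circ: Circuit, initial: StateVector) -> tuple[float, float]:
    """(p(y=0), p(y=1)) from measuring qubit 0 in the computational basis."""
    final = circ.run(initial)
    p1 = backend.measure_probability(final, 0, 1)
    return 1.0 - p1, p1


def predict_proba(learner: VariationalLearner, x: Sequence[float]) -> float:
    """Statevector-exact p(y=1) for one sample."""
    circ, state = build_ansatz(x, learner.theta)
    return readout_probability(circ, state)[1]


def bce_loss(p: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross entropy with probabilities clipped to [eps, 1-eps]."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ValueError("predictions and labels must have the same length")
    p = np.clip(p, EPS_CLIP, 1.0 - EPS_CLIP)
    return float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))


def parameter_shift_gradient(learner: VariationalLearner, X: np.ndarray,
                             y: np.ndarray) -> np.ndarray:
    """Analytic gradient of the batch BCE loss w.r.t. theta.

    Every parameter drives a single-qubit rotation (Pauli generator / 2), so
    dp/dtheta_j = [p(theta_j + pi/2) - p(theta_j - pi/2)] / 2 exactly; the
    chain rule through the clipped cross entropy gives the loss gradient.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    theta = learner.theta
    n_params = theta.size
    grad = np.zeros(n_params)
    n_samples = X.shape[0]
    for s in range(n_samples):
        p = predict_proba(learner, X[s])
        pc = np.clip(p, EPS_CLIP, 1.0 - EPS_CLIP)
        dl_dp = (pc - y[s]) / (pc * (1.0 - pc))
        for j in range(n_params):
            shifted = theta.copy()
            shifted[j] += np.pi / 2
            p_plus = predict_proba(replace(learner, theta=shifted), X[s])
            shifted[j] -= np.pi
            p_minus = predict_proba(replace(learner, theta=shifted), X[s])
            grad[j] += dl_dp * (p_plus - p_minus) / 2.0
    return grad / n_samples


@dataclass
class AdamState:
    m: np.ndarray
    v: np.ndarray
    t: int = 0


def adam_update(theta: np.ndarray, grad: np.ndarray, state: AdamState,
                cfg: TrainingConfig) -> np.ndarray:
    state.t += 1
    state.m = cfg.beta1 * state.m + (1 - cfg.beta1) * grad
    state.v = cfg.beta2 * state.v + (1 - cfg.beta2) * grad**2
    m_hat = state.m / (1 - cfg.beta1**state.t)
    v_hat = state.v / (1 - cfg.beta2**state.t)
    return theta - cfg.learning_rate * m_hat / (np.sqrt(v_hat) + cfg.adam_eps)


def train_learner(learner: VariationalLearner, X: np.ndarray, y: np.ndarray,
                  cfg: TrainingConfig,
                  rng: np.random.Generator | int | None = None
                  ) -> tuple[VariationalLearner, list[float]]:
    """Mini-batch Adam training; returns the trained learner and loss trace.

    Batches are drawn without replacement within each epoch (seeded shuffle);
    the trace records the full-data BCE loss once per epoch.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("training data is empty")
    rng = np.random.default_rng(cfg.seed if rng is None else rng) if not isinstance(
        rng, np.random.Generator
    ) else rng
    theta = learner.theta.copy()
    adam = AdamState(np.zeros_like(theta), np.zeros_like(theta))
    trace: list[float] = []
    n = X.shape[0]
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            current = replace(learner, theta=theta)
            grad = parameter_shift_gradient(current, X[idx], y[idx])
            theta = adam_update(theta, grad, adam, cfg)
        probs = np.array([predict_proba(replace(learner, theta=theta), xi) for xi in X])
        trace.append(bce_loss(probs, y))
    return replace(learner, theta=theta), trace


def kfold_indices(n: int, y: np.ndarray, k: int,
                  rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold (train_idx, val_idx) pairs with a seeded shuffle."""
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=int(rng.integers(2**31 - 1)))
    return [(tr, va) for tr, va in skf.split(np.zeros(n), y)]


def grid_search(X: np.ndarray, y: np.ndarray,
                grid: dict[str, Sequence] | None = None,
                epochs: int = 30, cv_folds: int = 4,
                seed: int | None = None) -> list[dict]:
    """k-fold cross-validated hyperparameter search for soft-voting ensembles.

    Returns one record per configuration with its median validation accuracy
    across folds, ranked descending. The default grid enumerates all
    learning-rate x batch-size x ensemble-size combinations (105 configs).
    """
    from .aggregate import Ensemble, soft_vote_fit  # local import: avoid cycle

    grid = dict(HYPERPARAMETER_GRID) if grid is None else grid
    configs = [
        dict(zip(grid.keys(), values)) for values in product(*grid.values())
    ]
    if not configs:
        raise ValueError("hyperparameter grid is empty")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    if cv_folds > X.shape[0]:
        raise ValueError("more folds than samples")
    folds = kfold_indices(X.shape[0], y, cv_folds, rng)

    results = []
    for conf in configs:
        cfg = TrainingConfig(epochs=epochs, cv_folds=cv_folds,
                             seed=int(rng.integers(2**31 - 1)), **conf)
        accs = []
        for tr, va in folds:
            ens = soft_vote_fit(X[tr], y[tr], cfg)
            preds = np.array([1 if ens.predict_proba(xi) >= 0.5 else 0 for xi in X[va]])
            accs.append(float(np.mean(preds == y[va])))
        results.append({**conf, "median_val_accuracy": float(np.median(accs)),
                        "fold_accuracies": accs})
    results.sort(key=lambda r: r["median_val_accuracy"], reverse=True)
    return results
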