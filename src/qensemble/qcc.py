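"""Quantum cosine classifier (QCC) — the swap-test weak learner.

One training sample and one test sample are amplitude-encoded into two data
registers; a swap test interferes them on a prediction ancilla, and a CNOT
from the basis-encoded training label conditions the readout, so that

    Pr(y_test = y_train) = 1/2 + D(x_train, x_test)^2 / 2

where D is the cosine similarity of the two (nonnegative) feature vectors.
An orthogonal pair gives a coin flip, an identical pair certainty, which is
exactly the weak-learner behaviour the ensemble constructions average over.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import backend
from .backend import StateVector, amplitude_encode, measure_probability, sample_shots
from .circuit import Circuit


@dataclass(frozen=True)
class QCCInstance:
    """One training sample (with binary label), one test sample, a shot budget."""

    x_train: np.ndarray
    y_train: int
    x_test: np.ndarray
    shots: int = 8192

    def __post_init__(self) -> None:
        xt = np.asarray(self.x_train, dtype=float)
        xs = np.asarray(self.x_test, dtype=float)
        object.__setattr__(self, "x_train", xt)
        object.__setattr__(self, "x_test", xs)
        if xt.shape != xs.shape:
            raise ValueError("train and test vectors must have the same length")
        if self.y_train not in (0, 1):
            raise ValueError("label must be binary")
        if self.shots <= 0:
            raise ValueError("shots must be positive")


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity <a,b>/(|a||b|) of two nonnegative vectors, in [0,1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have the same length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("vectors must be nonnegative")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for the zero vector")
    return float(np.dot(a, b) / (na * nb))


def analytic_probability(d: float) -> float:
    """Closed-form Pr(y_test = y_train) = 1/2 + D^2/2 for similarity D."""
    if not 0.0 <= d <= 1.0 + 1e-12:
        raise ValueError(f"similarity {d} outside [0, 1]")
    return 0.5 + min(d, 1.0) ** 2 / 2.0


def _encoded_width(n_features: int) -> int:
    return max(1, int(np.ceil(np.log2(n_features))))


def build_qcc_circuit(inst: QCCInstance) -> tuple[Circuit, StateVector, int]:
    """Assemble the QCC swap-test circuit.

    Register layout (little-endian, low to high): train data (m qubits),
    label (1 qubit), test data (m qubits), prediction ancilla (1 qubit),
    for m = log2 of the padded feature count — 4 qubits total at 2 features.

    Returns the circuit, the prepared initial state, and the ancilla index.
    """
    train_state = amplitude_encode(inst.x_train)
    test_state = amplitude_encode(inst.x_test)
    m = train_state.n_qubits
    n = 2 * m + 2
    label_q = m
    test_base = m + 1
    ancilla = n - 1

    label_state = backend.basis_state(1, inst.y_train)
    initial = (
        train_state.tensor(label_state).tensor(test_state).tensor(backend.basis_state(1))
    )

    circ = Circuit(n)
    circ.h(ancilla)
    for k in range(m):
        circ.cswap(ancilla, k, test_base + k)
    circ.h(ancilla)
    circ.cnot(label_q, ancilla)
    return circ, initial, ancilla


def predict_qcc(inst: QCCInstance, shots: int | None = None,
                rng: np.random.Generator | int | None = None) -> float:
    """Probability that the test sample is class 1.

    Statevector-exact by default; pass ``shots`` (and a seeded ``rng``) for a
    finite-sample estimate as observed 1-fraction on the prediction ancilla.
    """
    circ, initial, ancilla = build_qcc_circuit(inst)
    final = circ.run(initial)
    p = measure_probability(final, ancilla, 1)
    if shots is None:
        return p
    return sample_shots(p, shots, rng) / shots


def classify(p: float) -> int:
    """Hard label from a class-1 probability; ties at 0.5 go to class 1."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    return 1 if p >= 0.5 else 0
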