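"""Quantum ensemble cosine classifier (QEC) and its Haar-random variant.

The ensemble is built *inside* the circuit: d control qubits prepared in
uniform superposition entangle with 2d random transformations of the encoded
training block, creating B = 2^d quantum trajectories. Each trajectory moves
some training sample into slot 0, where a single swap-test cosine classifier
(the weak learner) interferes it with the test register. Because the control
branches are mutually orthogonal, the single ancilla measurement returns the
*average* weak-learner prediction over all 2^d trajectories — an exponential
ensemble from a linear number of extra qubits.

Register layout (little-endian, low to high), for n_train samples of
n_feature features (padded to 2^m):

    [slot-0 data .. slot-(n_train-1) data]  n_train * m qubits
    [labels, one basis qubit per slot]      n_train qubits
    [test data]                             m qubits
    [control register]                      d qubits
    [prediction ancilla]                    1 qubit

Two transformation families are supported: ``swap`` (each transformation is
a product of n_swap random sample-slot transpositions, moving data register
and matching label qubit together) and ``haar`` (each transformation is a
Haar-random unitary over the joint data subregisters, labels untouched).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import backend
from .backend import ResourceError, StateVector, amplitude_encode, measure_probability
from .circuit import Circuit
from .qcc import analytic_probability, cosine_similarity

#: parameter grids explored in the benchmark, per variant
QEC_GRID = {"d": (1, 2, 3), "n_train": (2, 4, 8), "n_swap": (1, 2, 4), "n_feature": (2, 4, 8)}
QECRU_GRID = {"d": (1, 2, 3), "n_train": (2, 4), "n_swap": (1, 2, 4), "n_feature": (2, 4, 8)}


@dataclass(frozen=True)
class QECConfig:
    """Structural parameters of one ensemble-cosine circuit."""

    d: int
    n_train: int
    n_feature: int
    n_swap: int = 1
    shots: int = 8192
    variant: str = "swap"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.d < 1 or self.n_train < 1 or self.n_feature < 1 or self.n_swap < 1:
            raise ValueError("all structural parameters must be positive")
        if self.shots <= 0:
            raise ValueError("shots must be positive")
        if self.variant not in ("swap", "haar"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "haar" and self.n_train * self.feature_qubits > backend.MAX_HAAR_QUBITS:
            raise ResourceError(
                "Haar transformation support "
                f"({self.n_train * self.feature_qubits} qubits) exceeds the "
                f"{backend.MAX_HAAR_QUBITS}-qubit cap"
            )

    @property
    def feature_qubits(self) -> int:
        """Qubits per data subregister, after padding to a power of two."""
        return max(1, int(np.ceil(np.log2(self.n_feature))))


def qec_width(cfg: QECConfig) -> int:
    """Total qubit count: data slots + label qubits + test + controls + ancilla.

    Scales as n_train * (log2 f + 1) + log2 f + d + 1 — logarithmic in the
    feature count, linear in training samples and control qubits.
    """
    m = cfg.feature_qubits
    return cfg.n_train * m + cfg.n_train + m + cfg.d + 1


def grid_widths(grid: dict[str, Sequence[int]], variant: str = "swap") -> list[int]:
    """Circuit widths of every configuration in a parameter grid."""
    widths = []
    for d in grid["d"]:
        for n_train in grid["n_train"]:
            for n_swap in grid["n_swap"]:
                for n_feature in grid["n_feature"]:
                    cfg = QECConfig.__new__(QECConfig)  # skip haar cap check
                    object.__setattr__(cfg, "d", d)
                    object.__setattr__(cfg, "n_train", n_train)
                    object.__setattr__(cfg, "n_feature", n_feature)
                    object.__setattr__(cfg, "n_swap", n_swap)
                    object.__setattr__(cfg, "shots", 8192)
                    object.__setattr__(cfg, "variant", variant)
                    object.__setattr__(cfg, "seed", None)
                    widths.append(qec_width(cfg))
    return widths


@dataclass(frozen=True)
class TrajectorySet:
    """The 2d sampled transformations (U_{i,1}, U_{i,2}) for i = 1..d.

    ``swap`` transformations are stored as slot-pair sequences; ``haar``
    transformations as dense matrices over the joint data subregisters.
    """

    variant: str
    transformations: tuple = field(default=())

    @property
    def d(self) -> int:
        return len(self.transformations)


def sample_slot_pairs(cfg: QECConfig, rng: np.random.Generator) -> tuple[tuple[int, int], ...]:
    """n_swap uniformly drawn (unordered) sample-slot transpositions."""
    if cfg.n_train < 2:
        raise ValueError("slot swaps need at least two training samples")
    pairs = []
    for _ in range(cfg.n_swap):
        a, b = rng.choice(cfg.n_train, size=2, replace=False)
        pairs.append((int(a), int(b)))
    return tuple(pairs)


def draw_trajectories(cfg: QECConfig, rng: np.random.Generator | int | None = None) -> TrajectorySet:
    """Sample the 2d transformations that define the ensemble's branches."""
    rng = np.random.default_rng(cfg.seed if rng is None else rng) if not isinstance(
        rng, np.random.Generator
    ) else rng
    pairs = []
    for _ in range(cfg.d):
        if cfg.variant == "swap":
            u1 = sample_slot_pairs(cfg, rng)
            u2 = sample_slot_pairs(cfg, rng)
        else:
            n_data = cfg.n_train * cfg.feature_qubits
            u1 = backend.sample_haar_unitary(n_data, rng).matrix
            u2 = backend.sample_haar_unitary(n_data, rng).matrix
        pairs.append((u1, u2))
    return TrajectorySet(cfg.variant, tuple(pairs))


def swap_transformation_matrix(cfg: QECConfig, pairs: Sequence[tuple[int, int]]) -> backend.UnitaryOp:
    """Materialize a slot-swap transformation as a permutation UnitaryOp.

    Acts on the joint (data subregisters + label qubits) block; each slot
    transposition exchanges a data subregister together with its label qubit.
    Intended for small blocks (contract checks and trajectory oracles).
    """
    m = cfg.feature_qubits
    block = cfg.n_train * (m + 1)
    if block > backend.MAX_HAAR_QUBITS:
        raise ResourceError(f"{block}-qubit permutation matrix exceeds materialization cap")
    dim = 2**block
    # qubit index within the block: data slot i at [i*m, (i+1)*m), label i at
    # n_train*m + i — mirrors the full-circuit layout.
    mat = np.eye(dim)
    for a, b in pairs:
        qubit_map = list(range(block))
        for k in range(m):
            qubit_map[a * m + k], qubit_map[b * m + k] = b * m + k, a * m + k
        la, lb = cfg.n_train * m + a, cfg.n_train * m + b
        qubit_map[la], qubit_map[lb] = lb, la
        step = np.zeros((dim, dim))
        for idx in range(dim):
            new = 0
            for q in range(block):
                if (idx >> q) & 1:
                    new |= 1 << qubit_map[q]
            step[new, idx] = 1.0
        mat = step @ mat
    return backend.UnitaryOp(mat, tuple(range(block)))


def _prepare_initial(cfg: QECConfig, train_X: np.ndarray, train_y: np.ndarray,
                     x_test: np.ndarray) -> StateVector:
    m = cfg.feature_qubits
    state = amplitude_encode(train_X[0])
    for i in range(1, cfg.n_train):
        state = state.tensor(amplitude_encode(train_X[i]))
    label_index = int(sum(int(y) << i for i, y in enumerate(train_y)))
    state = state.tensor(backend.basis_state(cfg.n_train, label_index))
    state = state.tensor(amplitude_encode(x_test))
    state = state.tensor(backend.basis_state(cfg.d + 1))  # controls + ancilla
    return state


def build_qec_circuit(cfg: QECConfig, train_X: np.ndarray, train_y: np.ndarray,
                      x_test: np.ndarray,
                      traj: TrajectorySet) -> tuple[Circuit, StateVector, int]:
    """Assemble the full ensemble circuit.

    Walsh–Hadamard on the controls; per control qubit i, controlled-U_{i,1}
    on control |1>, an X, controlled-U_{i,2}, and an X restoring the control
    (branch bit 1 selects U_{i,1}, bit 0 selects U_{i,2}); then the swap-test
    interference block between slot 0 and the test register with the slot-0
    label driving the prediction ancilla.
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y, dtype=int)
    if train_X.shape[0] != cfg.n_train:
        raise ValueError("training set size does not match config")
    width = qec_width(cfg)
    if width > backend.MAX_STATEVECTOR_QUBITS:
        raise ResourceError(
            f"{width}-qubit QEC circuit exceeds the "
            f"{backend.MAX_STATEVECTOR_QUBITS}-qubit simulation cap"
        )
    m = cfg.feature_qubits
    n_data = cfg.n_train * m
    label_base = n_data
    test_base = n_data + cfg.n_train
    control_base = test_base + m
    ancilla = width - 1

    circ = Circuit(width)
    for i in range(cfg.d):
        circ.h(control_base + i)

    def controlled_transformation(t, control: int) -> None:
        if cfg.variant == "swap":
            for a, b in t:
                for k in range(m):
                    circ.cswap(control, a * m + k, b * m + k)
                circ.cswap(control, label_base + a, label_base + b)
        else:
            circ.unitary(t, list(range(n_data)), [control])

    for i, (u1, u2) in enumerate(traj.transformations):
        ctrl = control_base + i
        controlled_transformation(u1, ctrl)
        circ.x(ctrl)
        controlled_transformation(u2, ctrl)
        circ.x(ctrl)

    # weak-learner interference block on slot 0
    circ.h(ancilla)
    for k in range(m):
        circ.cswap(ancilla, k, test_base + k)
    circ.h(ancilla)
    circ.cnot(label_base, ancilla)

    initial = _prepare_initial(cfg, train_X, train_y, x_test)
    return circ, initial, ancilla


def enumerate_trajectories(cfg: QECConfig, train_X: np.ndarray, train_y: np.ndarray,
                           x_test: np.ndarray, traj: TrajectorySet) -> np.ndarray:
    """Classical per-branch weak-learner probabilities (the ensemble oracle).

    For branch bitstring b, control qubit i contributes U_{i,1} if b_i = 1
    else U_{i,2}, composed in circuit order. For the swap variant the
    composition is a slot permutation and the branch value is the closed-form
    cosine probability of whichever sample lands in slot 0. For the haar
    variant the composed unitary is applied to the product-encoded data block
    and the branch value follows from the reduced slot-0 density matrix: a
    swap test against test state |t> accepts with (1 + <t|rho|t>)/2.
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y, dtype=int)
    m = cfg.feature_qubits
    probs = np.empty(2**cfg.d)
    test_vec = amplitude_encode(x_test).amplitudes

    if cfg.variant == "haar":
        data_block = amplitude_encode(train_X[0]).amplitudes
        for i in range(1, cfg.n_train):
            data_block = np.kron(amplitude_encode(train_X[i]).amplitudes, data_block)

    for b in range(2**cfg.d):
        chosen = [traj.transformations[i][0 if (b >> i) & 1 else 1] for i in range(cfg.d)]
        if cfg.variant == "swap":
            # slot s starts holding sample s; transpositions exchange contents
            content = list(range(cfg.n_train))
            for t in chosen:
                for a, bb in t:
                    content[a], content[bb] = content[bb], content[a]
            s0 = content[0]
            d_sim = cosine_similarity(train_X[s0], x_test)
            p1 = analytic_probability(d_sim)
            probs[b] = p1 if train_y[s0] == 1 else 1.0 - p1
        else:
            state = data_block
            dim_slot0 = 2**m
            for u in chosen:
                state = u @ state
            # reduced density matrix of slot 0 (lowest m qubits)
            resh = state.reshape(-1, dim_slot0)  # rows: other qubits, cols: slot 0
            rho = np.einsum("ai,aj->ij", resh, resh.conj())
            overlap = float(np.real(test_vec.conj() @ rho @ test_vec))
            p_match = 0.5 + overlap / 2.0
            probs[b] = p_match if train_y[0] == 1 else 1.0 - p_match
    return probs


def predict_qec(cfg: QECConfig, train_X: np.ndarray, train_y: np.ndarray,
                x_test: np.ndarray, traj: TrajectorySet | None = None,
                shots: int | None = None,
                rng: np.random.Generator | int | None = None) -> float:
    """Ensemble probability that the test sample is class 1.

    Statevector-exact by default (equals the mean over the 2^d trajectory
    probabilities); pass ``shots`` for a finite-sample estimate.
    """
    if traj is None:
        traj = draw_trajectories(cfg, rng=cfg.seed)
    circ, initial, ancilla = build_qec_circuit(cfg, train_X, train_y, x_test, traj)
    final = circ.run(initial)
    p = measure_probability(final, ancilla, 1)
    if shots is None:
        return p
    return backend.sample_shots(p, shots, rng) / shots


def predict_qecru(cfg: QECConfig, train_X: np.ndarray, train_y: np.ndarray,
                  x_test: np.ndarray, traj: TrajectorySet | None = None,
                  shots: int | None = None,
                  rng: np.random.Generator | int | None = None) -> float:
    """QEC with Haar-random transformations in place of the slot swaps."""
    if cfg.variant != "haar":
        raise ValueError("predict_qecru requires variant='haar'")
    return predict_qec(cfg, train_X, train_y, x_test, traj=traj, shots=shots, rng=rng)
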