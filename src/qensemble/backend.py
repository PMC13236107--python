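"""Statevector backend: state preparation, gate application, measurement.

The register is little-endian: qubit 0 is the least significant bit of the
amplitude index, so ``|q_{n-1} ... q_1 q_0>`` has index ``sum_k q_k 2^k``.
All classifier modules share this convention.

Multi-qubit gate matrices are likewise little-endian *within* the gate: for
``target_qubits = [t0, t1, ...]``, bit k of the gate's local basis index is
the state of ``t_k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

NORM_ATOL = 1e-10

#: Largest register a statevector is allocated for (2^24 amplitudes = 256 MB).
MAX_STATEVECTOR_QUBITS = 24

#: Largest Haar-random unitary that is materialized (2^12 x 2^12).
MAX_HAAR_QUBITS = 12


class EncodingError(ValueError):
    """Raised when a feature vector cannot be amplitude-encoded."""


class ResourceError(RuntimeError):
    """Raised when a requested circuit or matrix exceeds the simulable size."""


@dataclass(frozen=True)
class StateVector:
    """A pure state over ``n_qubits`` qubits, little-endian amplitude order."""

    amplitudes: np.ndarray
    n_qubits: int

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=complex)
        object.__setattr__(self, "amplitudes", amps)
        if amps.ndim != 1 or amps.size != 2**self.n_qubits:
            raise ValueError(
                f"amplitude vector of length {amps.size} does not match "
                f"{self.n_qubits} qubits"
            )
        norm = np.linalg.norm(amps)
        if abs(norm - 1.0) > 1e-8:
            raise ValueError(f"state is not normalized (norm={norm!r})")

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.amplitudes))

    def tensor(self, other: "StateVector") -> "StateVector":
        """Kronecker product placing ``other`` on the *higher* qubit indices."""
        return StateVector(
            np.kron(other.amplitudes, self.amplitudes),
            self.n_qubits + other.n_qubits,
        )


def basis_state(n_qubits: int, index: int = 0) -> StateVector:
    if n_qubits > MAX_STATEVECTOR_QUBITS:
        raise ResourceError(
            f"{n_qubits}-qubit statevector exceeds the "
            f"{MAX_STATEVECTOR_QUBITS}-qubit simulation cap"
        )
    amps = np.zeros(2**n_qubits, dtype=complex)
    amps[index] = 1.0
    return StateVector(amps, n_qubits)


@dataclass(frozen=True)
class UnitaryOp:
    """A unitary acting on ``target_qubits``, optionally controlled.

    The matrix has dimension ``2^len(target_qubits)``; control qubits gate the
    action on the subspace where every control is |1>.
    """

    matrix: np.ndarray
    target_qubits: tuple[int, ...]
    control_qubits: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=complex)
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(self, "target_qubits", tuple(self.target_qubits))
        object.__setattr__(self, "control_qubits", tuple(self.control_qubits))
        dim = 2 ** len(self.target_qubits)
        if mat.shape != (dim, dim):
            raise ValueError(
                f"matrix shape {mat.shape} does not match "
                f"{len(self.target_qubits)} target qubits"
            )
        if not _is_unitary(mat):
            raise ValueError("matrix is not unitary within 1e-10")
        touched = self.target_qubits + self.control_qubits
        if len(set(touched)) != len(touched):
            raise ValueError("target and control qubits must be distinct")


def _is_unitary(mat: np.ndarray, atol: float = NORM_ATOL) -> bool:
    dim = mat.shape[0]
    return bool(np.allclose(mat.conj().T @ mat, np.eye(dim), atol=atol * dim))


def amplitude_encode(x: Sequence[float]) -> StateVector:
    """Amplitude-encode a nonnegative feature vector.

    Vectors whose length is not a power of two are zero-padded up to the next
    power of two *before* normalization. Raises :class:`EncodingError` for
    all-zero or negative input (features are min-max scaled to [0, 1]
    upstream, so negative entries indicate a pipeline bug).
    """
    vec = np.asarray(x, dtype=float)
    if vec.ndim != 1 or vec.size == 0:
        raise EncodingError("feature vector must be a nonempty 1-D sequence")
    if np.any(vec < 0):
        raise EncodingError("feature vector has negative entries")
    peak = vec.max()
    if peak == 0:
        raise EncodingError("cannot amplitude-encode the all-zero vector")
    vec = vec / peak  # rescale first so the norm cannot underflow
    norm = np.linalg.norm(vec)
    n_qubits = max(1, int(np.ceil(np.log2(vec.size))))
    padded = np.zeros(2**n_qubits, dtype=complex)
    padded[: vec.size] = vec
    return StateVector(padded / norm, n_qubits)


def apply(state: StateVector, op: UnitaryOp) -> StateVector:
    """Apply ``op`` to ``state`` and return the new state (norm preserved)."""
    n = state.n_qubits
    for q in op.target_qubits + op.control_qubits:
        if not 0 <= q < n:
            raise ValueError(f"qubit index {q} outside register of size {n}")

    k = len(op.target_qubits)
    # Reshape to one axis per qubit. With C order, axis j corresponds to
    # qubit n-1-j, so qubit q lives on axis n-1-q.
    tensor = state.amplitudes.reshape([2] * n)

    if op.control_qubits:
        sel: list[object] = [slice(None)] * n
        for c in op.control_qubits:
            sel[n - 1 - c] = 1
        sub = tensor[tuple(sel)].copy()
        sub_qubits = [q for q in range(n) if q not in op.control_qubits]
        new_sub = _apply_to_tensor(sub, op.matrix, op.target_qubits, sub_qubits)
        out = tensor.copy()
        out[tuple(sel)] = new_sub
    else:
        out = _apply_to_tensor(tensor, op.matrix, op.target_qubits, list(range(n)))
    return StateVector(out.reshape(-1), n)


def _apply_to_tensor(
    tensor: np.ndarray,
    matrix: np.ndarray,
    targets: Sequence[int],
    tensor_qubits: Sequence[int],
) -> np.ndarray:
    """Apply ``matrix`` to the axes of ``tensor`` holding ``targets``.

    ``tensor_qubits`` lists, in increasing qubit order, which register qubit
    each remaining tensor dimension belongs to (axes are reversed: axis 0 is
    the highest qubit).
    """
    m = len(tensor_qubits)
    axis_of = {q: m - 1 - i for i, q in enumerate(tensor_qubits)}
    # Gate-local bit k = targets[k]; make targets the *last* axes in
    # little-endian order (target[0] innermost).
    tgt_axes = [axis_of[q] for q in targets]
    rest = [a for a in range(m) if a not in tgt_axes]
    perm = rest + tgt_axes[::-1]
    moved = np.transpose(tensor, perm)
    k = len(targets)
    shape = moved.shape
    flat = moved.reshape(-1, 2**k)
    flat = flat @ matrix.T
    moved = flat.reshape(shape)
    return np.transpose(moved, np.argsort(perm))


def measure_probability(state: StateVector, qubit: int, outcome: int) -> float:
    """Probability of observing ``outcome`` on ``qubit`` (Born rule)."""
    if not 0 <= qubit < state.n_qubits:
        raise ValueError(f"qubit index {qubit} outside register")
    if outcome not in (0, 1):
        raise ValueError("outcome must be 0 or 1")
    n = state.n_qubits
    tensor = np.abs(state.amplitudes.reshape([2] * n)) ** 2
    sel: list[object] = [slice(None)] * n
    sel[n - 1 - qubit] = outcome
    return float(tensor[tuple(sel)].sum())


def sample_shots(p: float, shots: int, rng: np.random.Generator | int | None = None) -> int:
    """Number of 1-outcomes in ``shots`` Bernoulli(p) measurements."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    if shots <= 0:
        raise ValueError("shots must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return int(rng.binomial(shots, p))


def sample_haar_unitary(
    n_qubits: int, rng: np.random.Generator | int | None = None
) -> UnitaryOp:
    """Draw a Haar-distributed unitary on ``n_qubits`` qubits.

    A standard-normal complex matrix is QR-decomposed and the orthogonal
    factor's columns are phase-normalized by the diagonal of R, which makes
    the resulting distribution the unique left- and right-invariant (Haar)
    measure on U(2^n).
    """
    if n_qubits < 1:
        raise ValueError("n_qubits must be >= 1")
    if n_qubits > MAX_HAAR_QUBITS:
        raise ResourceError(
            f"Haar sampling on {n_qubits} qubits exceeds the "
            f"{MAX_HAAR_QUBITS}-qubit cap"
        )
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    dim = 2**n_qubits
    z = (rng.standard_normal((dim, dim)) + 1j * rng.standard_normal((dim, dim))) / np.sqrt(2)
    q, r = np.linalg.qr(z)
    d = np.diagonal(r)
    q = q * (d / np.abs(d))
    return UnitaryOp(q, tuple(range(n_qubits)))


# Fixed 2x2 / 4x4 gate constants used across the classifier circuits.
H = np.array([[1, 1], [1, -1]], dtype=complex) / np.sqrt(2)
X = np.array([[0, 1], [1, 0]], dtype=complex)
SWAP = np.array(
    [[1, 0, 0, 0], [0, 0, 1, 0], [0, 1, 0, 0], [0, 0, 0, 1]], dtype=complex
)


def rz(theta: float) -> np.ndarray:
    return np.array(
        [[np.exp(-0.5j * theta), 0], [0, np.exp(0.5j * theta)]], dtype=complex
    )


def ry(theta: float) -> np.ndarray:
    c, s = np.cos(theta / 2), np.sin(theta / 2)
    return np.array([[c, -s], [s, c]], dtype=complex)
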