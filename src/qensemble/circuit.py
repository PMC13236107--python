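"""Minimal gate-list circuit on top of the statevector backend."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import backend
from .backend import StateVector, UnitaryOp


class Circuit:
    """An ordered list of unitaries over a fixed-width register.

    The initial state defaults to |0...0> and can be overridden at ``run``
    time, which is how the classifiers inject their amplitude-encoded
    registers.
    """

    def __init__(self, n_qubits: int):
        if n_qubits < 1:
            raise ValueError("circuit needs at least one qubit")
        if n_qubits > backend.MAX_STATEVECTOR_QUBITS:
            raise backend.ResourceError(
                f"{n_qubits}-qubit circuit exceeds the "
                f"{backend.MAX_STATEVECTOR_QUBITS}-qubit simulation cap"
            )
        self.n_qubits = n_qubits
        self.ops: list[UnitaryOp] = []

    def append(self, op: UnitaryOp) -> "Circuit":
        self.ops.append(op)
        return self

    def unitary(
        self,
        matrix: np.ndarray,
        targets: Sequence[int],
        controls: Sequence[int] = (),
    ) -> "Circuit":
        return self.append(UnitaryOp(matrix, tuple(targets), tuple(controls)))

    def h(self, q: int) -> "Circuit":
        return self.unitary(backend.H, [q])

    def x(self, q: int) -> "Circuit":
        return self.unitary(backend.X, [q])

    def cnot(self, control: int, target: int) -> "Circuit":
        return self.unitary(backend.X, [target], [control])

    def swap(self, a: int, b: int) -> "Circuit":
        return self.unitary(backend.SWAP, [a, b])

    def cswap(self, control: int, a: int, b: int) -> "Circuit":
        return self.unitary(backend.SWAP, [a, b], [control])

    def run(self, initial: StateVector | None = None) -> StateVector:
        state = initial if initial is not None else backend.basis_state(self.n_qubits)
        if state.n_qubits != self.n_qubits:
            raise ValueError("initial state width does not match circuit")
        for op in self.ops:
            state = backend.apply(state, op)
        return state
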