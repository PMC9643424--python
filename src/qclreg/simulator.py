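"""Dense statevector simulation of few-qubit circuits.

The engine keeps the full complex amplitude vector over the ``2**n``
computational basis states and evolves it exactly, gate by gate.  Readout is
the expectation of the Pauli-Z observable on a single qubit, either computed
directly from the amplitudes (``shots=EXACT``) or estimated from a finite
number of projective measurements drawn binomially.

Conventions
-----------
* Half-angle rotations: ``RY(t) = exp(-i t Y / 2)``, ``RZ(t) = exp(-i t Z / 2)``,
  so ``<Z> = cos(t)`` after ``RY(t)|0>``.
* ``U3(theta, phi, lam) = RZ(phi) @ RY(theta) @ RZ(lam)`` up to global phase;
  every angle is therefore the angle of a Pauli rotation, which is what the
  parameter-shift rule requires.
* Little-endian qubit ordering: bit ``k`` of a basis-state index is qubit
  ``k``; qubit 0 is the top wire of a circuit diagram.

There is no global random state: every stochastic operation takes an
explicit :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "EXACT",
    "Gate",
    "StateVector",
    "ExpectationEstimate",
    "apply_gate",
    "gate_matrix",
    "z_expectation_exact",
    "z_expectation_sampled",
]

#: Sentinel for infinite-shot (statevector) readout.
EXACT = "exact"

#: Number of angle parameters carried by each gate kind.
GATE_N_ANGLES = {"RY": 1, "RZ": 1, "U3": 3, "CNOT": 0}


@dataclass(frozen=True)
class Gate:
    """A single gate: RY, RZ, U3 (three angles) or CNOT.

    ``trainable`` flags each angle as a trainable slot or a fixed (encoding)
    angle; it is bookkeeping only — application ignores it.
    """

    kind: str
    target: int
    control: int | None = None
    angles: tuple[float, ...] = ()
    trainable: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in GATE_N_ANGLES:
            raise ValueError(f"unknown gate kind {self.kind!r}")
        n_angles = GATE_N_ANGLES[self.kind]
        if len(self.angles) != n_angles:
            raise ValueError(
                f"{self.kind} takes {n_angles} angle(s), got {len(self.angles)}"
            )
        if not all(math.isfinite(a) for a in self.angles):
            raise ValueError(f"non-finite angle in {self.kind}: {self.angles}")
        if self.kind == "CNOT":
            if self.control is None:
                raise ValueError("CNOT requires a control qubit")
            if self.control == self.target:
                raise ValueError("CNOT control and target must differ")
        elif self.control is not None:
            raise ValueError(f"{self.kind} does not take a control qubit")
        if not self.trainable:
            object.__setattr__(self, "trainable", (False,) * n_angles)
        elif len(self.trainable) != n_angles:
            raise ValueError("trainable flags must match the number of angles")

    def with_angles(self, angles: tuple[float, ...]) -> "Gate":
        return Gate(self.kind, self.target, self.control, tuple(angles), self.trainable)


@dataclass
class StateVector:
    """Unit-norm complex amplitudes over the 2**n_qubits basis states."""

    amplitudes: np.ndarray
    n_qubits: int

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.complex128)
        if self.amplitudes.shape != (2**self.n_qubits,):
            raise ValueError(
                f"expected {2**self.n_qubits} amplitudes for {self.n_qubits} "
                f"qubits, got shape {self.amplitudes.shape}"
            )
        norm = np.linalg.norm(self.amplitudes)
        if abs(norm - 1.0) > 1e-8:
            raise ValueError(f"state norm {norm} deviates from 1")

    @classmethod
    def zero(cls, n_qubits: int) -> "StateVector":
        """The all-|0> computational basis state."""
        if n_qubits < 1:
            raise ValueError("n_qubits must be positive")
        amps = np.zeros(2**n_qubits, dtype=np.complex128)
        amps[0] = 1.0
        return cls(amps, n_qubits)

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.amplitudes))


@dataclass(frozen=True)
class ExpectationEstimate:
    """A Pauli-Z expectation: exact, or a finite-shot binomial estimate.

    When ``shots`` is finite, ``value = (2 * n_zero - shots) / shots`` with
    ``n_zero`` the number of |0> outcomes on the readout qubit.
    """

    value: float
    shots: int | str
    n_zero: int | None = None

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.value <= 1.0 + 1e-12:
            raise ValueError(f"expectation {self.value} outside [-1, 1]")


def _ry_matrix(t: float) -> np.ndarray:
    c, s = math.cos(t / 2.0), math.sin(t / 2.0)
    return np.array([[c, -s], [s, c]], dtype=np.complex128)


def _rz_matrix(t: float) -> np.ndarray:
    e = np.exp(-0.5j * t)
    return np.array([[e, 0.0], [0.0, np.conj(e)]], dtype=np.complex128)


def gate_matrix(gate: Gate) -> np.ndarray:
    """The 2x2 unitary of a single-qubit gate (CNOT has no 2x2 matrix)."""
    if gate.kind == "RY":
        return _ry_matrix(gate.angles[0])
    if gate.kind == "RZ":
        return _rz_matrix(gate.angles[0])
    if gate.kind == "U3":
        theta, phi, lam = gate.angles
        return _rz_matrix(phi) @ _ry_matrix(theta) @ _rz_matrix(lam)
    raise ValueError(f"no single-qubit matrix for {gate.kind}")


@lru_cache(maxsize=None)
def _cnot_permutation(n_qubits: int, control: int, target: int) -> np.ndarray:
    idx = np.arange(2**n_qubits)
    flipped = idx ^ (1 << target)
    control_on = (idx >> control) & 1 == 1
    return np.where(control_on, flipped, idx)


def _apply_single_qubit(amps: np.ndarray, n_qubits: int, qubit: int, m: np.ndarray) -> np.ndarray:
    # little-endian: qubit k is axis (n-1-k) of the C-ordered tensor
    axis = n_qubits - 1 - qubit
    t = amps.reshape((2,) * n_qubits)
    t = np.tensordot(m, t, axes=([1], [axis]))
    t = np.moveaxis(t, 0, axis)
    return t.reshape(-1)


def apply_gate(state: StateVector, gate: Gate) -> StateVector:
    """Apply one gate, returning a new unit-norm state."""
    n = state.n_qubits
    if not 0 <= gate.target < n:
        raise IndexError(f"target qubit {gate.target} out of range for {n} qubits")
    if gate.kind == "CNOT":
        if not 0 <= gate.control < n:
            raise IndexError(f"control qubit {gate.control} out of range for {n} qubits")
        perm = _cnot_permutation(n, gate.control, gate.target)
        out = state.amplitudes[perm]
    else:
        out = _apply_single_qubit(state.amplitudes, n, gate.target, gate_matrix(gate))
    return StateVector(out, n)


def apply_gates(state: StateVector, gates) -> StateVector:
    """Apply an ordered gate sequence (gate-loop without re-validation cost)."""
    amps = state.amplitudes
    n = state.n_qubits
    for gate in gates:
        if gate.kind == "CNOT":
            if not 0 <= gate.control < n or not 0 <= gate.target < n:
                raise IndexError("CNOT qubit index out of range")
            amps = amps[_cnot_permutation(n, gate.control, gate.target)]
        else:
            if not 0 <= gate.target < n:
                raise IndexError(f"target qubit {gate.target} out of range")
            amps = _apply_single_qubit(amps, n, gate.target, gate_matrix(gate))
    return StateVector(amps, n)


def _prob_zero(state: StateVector, qubit: int) -> float:
    if not 0 <= qubit < state.n_qubits:
        raise IndexError(f"qubit {qubit} out of range for {state.n_qubits} qubits")
    idx = np.arange(2**state.n_qubits)
    mask = (idx >> qubit) & 1 == 0
    p0 = float(np.sum(np.abs(state.amplitudes[mask]) ** 2))
    return min(max(p0, 0.0), 1.0)


def z_expectation_exact(state: StateVector, qubit: int) -> ExpectationEstimate:
    """<Z> on one qubit computed directly from the statevector."""
    p0 = _prob_zero(state, qubit)
    return ExpectationEstimate(value=2.0 * p0 - 1.0, shots=EXACT)


def z_expectation_sampled(
    state: StateVector, qubit: int, shots: int, rng: np.random.Generator
) -> ExpectationEstimate:
    """Finite-shot <Z> estimate: n_zero ~ Binomial(shots, P(qubit = 0))."""
    if not isinstance(shots, (int, np.integer)) or shots < 1:
        raise ValueError(f"shots must be a positive integer, got {shots!r}")
    p0 = _prob_zero(state, qubit)
    n_zero = int(rng.binomial(int(shots), p0))
    value = (2.0 * n_zero - shots) / shots
    return ExpectationEstimate(value=value, shots=int(shots), n_zero=n_zero)
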