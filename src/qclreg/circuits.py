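"""Encoding circuit and the two variational ansätze (layered and MERA).

The encoder embeds a scaled descriptor vector ``x`` (each entry in
``[-pi, pi]``) as rotation angles ``RY(x_i)`` then ``RZ(x_i)`` on qubit
``i``, followed by a CNOT entangling chain; the rotation/CNOT block is
repeated (twice by default).  It carries no trainable parameters.

Two trainable circuits act on the encoded state:

* the *layered* ("original") ansatz — ``L`` layers of a CNOT chain followed
  by one generic U3 rotation per qubit, hence ``3 * n_qubits * L`` trainable
  angles, with Z-readout on the last wire;
* the 4-qubit *MERA* ansatz — four two-qubit blocks (disentangler on wires
  1-2, isometries on 0-1 and 2-3, top block on 1-2), each a U3 on both wires
  followed by a CNOT, hence 8 U3 gates = 24 trainable angles, with readout
  on wire 2 (the circuit's "third qubit").

Trainable parameters are addressed by ordered *slots* ``(gate index, angle
index)``; :func:`bind_parameters` writes a flat parameter vector into the
slots in that canonical order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .simulator import EXACT, Gate, StateVector, apply_gates

__all__ = [
    "ParameterizedCircuit",
    "EncodingSpec",
    "build_encoder",
    "build_original_ansatz",
    "build_mera_ansatz",
    "bind_parameters",
    "random_initial_theta",
    "encode_state",
    "run_circuit",
]


@dataclass(frozen=True)
class ParameterizedCircuit:
    """An ordered gate sequence with named trainable slots and a readout qubit."""

    n_qubits: int
    gates: tuple[Gate, ...]
    trainable_slots: tuple[tuple[int, int], ...]
    readout_qubit: int

    def __post_init__(self) -> None:
        if not 0 <= self.readout_qubit < self.n_qubits:
            raise ValueError(f"readout qubit {self.readout_qubit} out of range")
        seen = set()
        for gi, ai in self.trainable_slots:
            if not 0 <= gi < len(self.gates):
                raise ValueError(f"slot gate index {gi} out of range")
            if not 0 <= ai < len(self.gates[gi].angles):
                raise ValueError(f"slot angle index {ai} out of range for gate {gi}")
            if (gi, ai) in seen:
                raise ValueError(f"duplicate trainable slot ({gi}, {ai})")
            seen.add((gi, ai))

    @property
    def n_trainable(self) -> int:
        return len(self.trainable_slots)

    @property
    def theta(self) -> np.ndarray:
        """Current values of the trainable angles, in canonical slot order."""
        return np.array([self.gates[gi].angles[ai] for gi, ai in self.trainable_slots])

    def to_dict(self) -> dict:
        return {
            "n_qubits": self.n_qubits,
            "gates": [
                {
                    "kind": g.kind,
                    "target": g.target,
                    "control": g.control,
                    "angles": list(g.angles),
                    "trainable": list(g.trainable),
                }
                for g in self.gates
            ],
            "trainable_slots": [list(s) for s in self.trainable_slots],
            "readout_qubit": self.readout_qubit,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterizedCircuit":
        gates = tuple(
            Gate(
                kind=g["kind"],
                target=g["target"],
                control=g.get("control"),
                angles=tuple(g.get("angles", ())),
                trainable=tuple(bool(t) for t in g.get("trainable", ())),
            )
            for g in d["gates"]
        )
        return cls(
            n_qubits=d["n_qubits"],
            gates=gates,
            trainable_slots=tuple((int(a), int(b)) for a, b in d["trainable_slots"]),
            readout_qubit=d["readout_qubit"],
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "ParameterizedCircuit":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class EncodingSpec:
    """Encoder shape: one qubit per retained principal component.

    ``entangler`` selects the CNOT topology of each entangling block:
    ``"linear"`` is the chain CNOT(0->1), ..., CNOT(n-2 -> n-1); ``"ring"``
    closes it with CNOT(n-1 -> 0).
    """

    n_qubits: int = 4
    repetitions: int = 2
    entangler: str = "linear"

    def __post_init__(self) -> None:
        if self.n_qubits < 1:
            raise ValueError("n_qubits must be positive")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.entangler not in ("linear", "ring"):
            raise ValueError(f"unknown entangler {self.entangler!r}")


def _cnot_chain(n_qubits: int, entangler: str) -> list[Gate]:
    gates = [Gate("CNOT", target=q + 1, control=q) for q in range(n_qubits - 1)]
    if entangler == "ring" and n_qubits > 1:
        gates.append(Gate("CNOT", target=0, control=n_qubits - 1))
    return gates


def build_encoder(x_scaled: np.ndarray, spec: EncodingSpec | None = None) -> ParameterizedCircuit:
    """Encoding circuit for one scaled sample; zero trainable slots.

    Raises ``ValueError`` when an angle falls outside ``[-pi, pi]`` — a sign
    that min–max preprocessing was skipped.
    """
    spec = spec or EncodingSpec()
    x = np.asarray(x_scaled, dtype=float)
    if x.shape != (spec.n_qubits,):
        raise ValueError(f"expected {spec.n_qubits} angles, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite encoding angle")
    if np.any(np.abs(x) > math.pi + 1e-9):
        raise ValueError(
            "encoding angles must lie in [-pi, pi]; apply min-max scaling first"
        )
    gates: list[Gate] = []
    for _ in range(spec.repetitions):
        for q in range(spec.n_qubits):
            gates.append(Gate("RY", target=q, angles=(float(x[q]),)))
            gates.append(Gate("RZ", target=q, angles=(float(x[q]),)))
        gates.extend(_cnot_chain(spec.n_qubits, spec.entangler))
    return ParameterizedCircuit(
        n_qubits=spec.n_qubits,
        gates=tuple(gates),
        trainable_slots=(),
        readout_qubit=spec.n_qubits - 1,
    )


def build_original_ansatz(
    n_qubits: int = 4, L: int = 1, entangler: str = "linear"
) -> ParameterizedCircuit:
    """Layered ansatz: L x (CNOT chain, then U3 per qubit); 3*n_qubits*L params.

    Readout is the Z expectation on the last wire.
    """
    if L < 1:
        raise ValueError("number of layers L must be >= 1")
    if n_qubits < 2:
        raise ValueError("layered ansatz needs at least 2 qubits")
    gates: list[Gate] = []
    slots: list[tuple[int, int]] = []
    for _ in range(L):
        gates.extend(_cnot_chain(n_qubits, entangler))
        for q in range(n_qubits):
            gi = len(gates)
            gates.append(
                Gate("U3", target=q, angles=(0.0, 0.0, 0.0), trainable=(True,) * 3)
            )
            slots.extend([(gi, 0), (gi, 1), (gi, 2)])
    return ParameterizedCircuit(
        n_qubits=n_qubits,
        gates=tuple(gates),
        trainable_slots=tuple(slots),
        readout_qubit=n_qubits - 1,
    )


#: MERA two-qubit blocks on 4 wires as (control, target) pairs: disentangler
#: on (1,2), isometries on (0,1) and (3,2), top block on (1,2).  CNOT targets
#: point toward the readout wire so every U3 lies in its causal cone — a CNOT
#: never changes the Z marginal of its own control.
_MERA_BLOCKS = ((1, 2), (0, 1), (3, 2), (1, 2))


def build_mera_ansatz(n_qubits: int = 4) -> ParameterizedCircuit:
    """4-qubit MERA ansatz: 8 U3 gates (24 params), readout on wire 2."""
    if n_qubits != 4:
        raise ValueError("the MERA ansatz is defined for exactly 4 qubits")
    gates: list[Gate] = []
    slots: list[tuple[int, int]] = []
    for a, b in _MERA_BLOCKS:
        for q in (a, b):
            gi = len(gates)
            gates.append(
                Gate("U3", target=q, angles=(0.0, 0.0, 0.0), trainable=(True,) * 3)
            )
            slots.extend([(gi, 0), (gi, 1), (gi, 2)])
        gates.append(Gate("CNOT", target=b, control=a))
    return ParameterizedCircuit(
        n_qubits=4,
        gates=tuple(gates),
        trainable_slots=tuple(slots),
        readout_qubit=2,
    )


def bind_parameters(circuit: ParameterizedCircuit, theta: np.ndarray) -> ParameterizedCircuit:
    """Write a flat parameter vector into the trainable slots (canonical order)."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (circuit.n_trainable,):
        raise ValueError(
            f"expected {circuit.n_trainable} parameters, got shape {theta.shape}"
        )
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite parameter value")
    new_angles: dict[int, list[float]] = {}
    for (gi, ai), value in zip(circuit.trainable_slots, theta):
        new_angles.setdefault(gi, list(circuit.gates[gi].angles))[ai] = float(value)
    gates = list(circuit.gates)
    for gi, angles in new_angles.items():
        gates[gi] = gates[gi].with_angles(tuple(angles))
    return replace(circuit, gates=tuple(gates))


def random_initial_theta(
    circuit: ParameterizedCircuit, rng: np.random.Generator
) -> np.ndarray:
    """Random start: i.i.d. uniform angles on [0, 2*pi)."""
    return rng.uniform(0.0, 2.0 * math.pi, size=circuit.n_trainable)


def run_circuit(
    circuit: ParameterizedCircuit, state: StateVector | None = None
) -> StateVector:
    """Run the circuit on ``state`` (default |0...0>), returning the final state."""
    if state is None:
        state = StateVector.zero(circuit.n_qubits)
    elif state.n_qubits != circuit.n_qubits:
        raise ValueError("state and circuit qubit counts differ")
    return apply_gates(state, circuit.gates)


def encode_state(x_scaled: np.ndarray, spec: EncodingSpec | None = None) -> StateVector:
    """Encoder output state for one scaled sample (cacheable per sample)."""
    return run_circuit(build_encoder(x_scaled, spec))
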