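"""Statevector engine: gate semantics, norm conservation, Z readout."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qclreg.simulator import (
    EXACT,
    Gate,
    StateVector,
    apply_gate,
    apply_gates,
    gate_matrix,
    z_expectation_exact,
    z_expectation_sampled,
)


def test_zero_state_reads_plus_one_on_every_qubit():
    state = StateVector.zero(4)
    for qubit in range(4):
        assert z_expectation_exact(state, qubit).value == pytest.approx(1.0)


@pytest.mark.parametrize(
    "angle, expected",
    [(math.pi, -1.0), (math.pi / 2, 0.0), (2 * math.pi / 3, math.cos(2 * math.pi / 3))],
)
def test_ry_rotation_gives_cosine_expectation(angle, expected):
    """<Z> = cos(theta) after RY(theta)|0> under the half-angle convention."""
    state = apply_gate(StateVector.zero(1), Gate("RY", 0, angles=(angle,)))
    assert z_expectation_exact(state, 0).value == pytest.approx(expected, abs=1e-12)


def test_cnot_truth_table_little_endian():
    # |01> (qubit 0 set) --CNOT(0->1)--> |11> = index 3
    state = apply_gate(StateVector.zero(2), Gate("RY", 0, angles=(math.pi,)))
    flipped = apply_gate(state, Gate("CNOT", target=1, control=0))
    assert np.abs(flipped.amplitudes[3]) == pytest.approx(1.0)
    # control clear leaves the target alone
    untouched = apply_gate(StateVector.zero(2), Gate("CNOT", target=0, control=1))
    assert np.abs(untouched.amplitudes[0]) == pytest.approx(1.0)


def test_ghz_state_has_zero_z_expectation_everywhere():
    state = apply_gate(StateVector.zero(4), Gate("RY", 0, angles=(math.pi / 2,)))
    for q in range(3):
        state = apply_gate(state, Gate("CNOT", target=q + 1, control=q))
    for qubit in range(4):
        assert z_expectation_exact(state, qubit).value == pytest.approx(0.0, abs=1e-12)


@st.composite
def random_gates(draw, n_qubits=3, max_len=12):
    gates = []
    for _ in range(draw(st.integers(1, max_len))):
        kind = draw(st.sampled_from(["RY", "RZ", "U3", "CNOT"]))
        target = draw(st.integers(0, n_qubits - 1))
        if kind == "CNOT":
            control = draw(
                st.integers(0, n_qubits - 1).filter(lambda c: c != target)
            )
            gates.append(Gate("CNOT", target=target, control=control))
        else:
            angles = tuple(
                draw(st.floats(-2 * math.pi, 2 * math.pi, allow_nan=False))
                for _ in range(3 if kind == "U3" else 1)
            )
            gates.append(Gate(kind, target=target, angles=angles))
    return gates


@settings(max_examples=60, deadline=None, derandomize=True)
@given(random_gates())
def test_norm_conserved_under_any_gate_sequence(gates):
    state = apply_gates(StateVector.zero(3), gates)
    assert abs(state.norm - 1.0) < 1e-10


@settings(max_examples=60, deadline=None, derandomize=True)
@given(random_gates())
def test_gate_then_inverse_restores_state(gates):
    """Unitarity: negated angles (CNOT is its own inverse) undo the circuit."""
    state = apply_gates(StateVector.zero(3), gates)
    inverse = []
    for g in reversed(gates):
        if g.kind == "CNOT":
            inverse.append(g)
        elif g.kind == "U3":
            theta, phi, lam = g.angles
            inverse.append(Gate("U3", g.target, angles=(-theta, -lam, -phi)))
        else:
            inverse.append(Gate(g.kind, g.target, angles=(-g.angles[0],)))
    restored = apply_gates(state, inverse)
    np.testing.assert_allclose(
        restored.amplitudes, StateVector.zero(3).amplitudes, atol=1e-10
    )


def test_cnot_is_an_involution(rng):
    amps = rng.normal(size=8) + 1j * rng.normal(size=8)
    amps /= np.linalg.norm(amps)
    state = StateVector(amps, 3)
    g = Gate("CNOT", target=2, control=0)
    twice = apply_gate(apply_gate(state, g), g)
    np.testing.assert_allclose(twice.amplitudes, amps, atol=1e-12)


def test_gate_matrices_are_unitary():
    for gate in (
        Gate("RY", 0, angles=(0.7,)),
        Gate("RZ", 0, angles=(-1.3,)),
        Gate("U3", 0, angles=(0.4, 1.1, -2.0)),
    ):
        m = gate_matrix(gate)
        np.testing.assert_allclose(m @ m.conj().T, np.eye(2), atol=1e-12)


class TestSampledReadout:
    def test_degenerate_distribution_is_exact(self, rng):
        est = z_expectation_sampled(StateVector.zero(3), 1, shots=50, rng=rng)
        assert est.value == 1.0 and est.n_zero == 50

    def test_value_matches_counting_invariant(self, rng):
        state = apply_gate(StateVector.zero(1), Gate("RY", 0, angles=(1.0,)))
        est = z_expectation_sampled(state, 0, shots=173, rng=rng)
        assert est.value == pytest.approx((2 * est.n_zero - 173) / 173)

    def test_deterministic_under_fixed_seed(self):
        state = apply_gate(StateVector.zero(1), Gate("RY", 0, angles=(1.0,)))
        a = z_expectation_sampled(state, 0, 100, np.random.default_rng(7)).value
        b = z_expectation_sampled(state, 0, 100, np.random.default_rng(7)).value
        assert a == b

    @pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
    def test_estimator_is_unbiased(self, p):
        """Mean over 500 repeated estimates stays within 4 binomial SEs."""
        theta = 2.0 * math.acos(math.sqrt(p))  # P(|0>) = cos^2(theta/2) = p
        state = apply_gate(StateVector.zero(1), Gate("RY", 0, angles=(theta,)))
        exact = z_expectation_exact(state, 0).value
        rng = np.random.default_rng(99)
        shots = 100
        values = [z_expectation_sampled(state, 0, shots, rng).value for _ in range(500)]
        se = math.sqrt(p * (1 - p) / shots)
        assert abs(np.mean(values) - exact) <= 4 * se

    def test_large_shot_count_converges_to_exact(self):
        state = apply_gate(StateVector.zero(1), Gate("RY", 0, angles=(math.pi / 2,)))
        est = z_expectation_sampled(state, 0, 10**6, np.random.default_rng(3))
        assert abs(est.value - 0.0) < 5e-3


class TestValidation:
    def test_bad_qubit_index_raises(self):
        with pytest.raises(IndexError):
            apply_gate(StateVector.zero(2), Gate("RY", 5, angles=(0.1,)))
        with pytest.raises(IndexError):
            z_expectation_exact(StateVector.zero(2), 2)

    def test_nonfinite_angle_rejected(self):
        with pytest.raises(ValueError):
            Gate("RY", 0, angles=(float("nan"),))

    def test_wrong_angle_count_rejected(self):
        with pytest.raises(ValueError):
            Gate("U3", 0, angles=(0.1,))
        with pytest.raises(ValueError):
            Gate("CNOT", 0, control=0)

    def test_nonpositive_shots_rejected(self, rng):
        with pytest.raises(ValueError):
            z_expectation_sampled(StateVector.zero(1), 0, 0, rng)
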