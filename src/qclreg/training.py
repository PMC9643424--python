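"""Loss, gradients and optimizers for quantum circuit learning.

The model prediction for one sample is the Z expectation ``B(theta)`` of the
readout qubit after running encoder(x) then ansatz(theta) on |0...0>.  The
objective is the mean squared error between the squashed target and ``B``.

Two optimizers are provided, mirroring the two training regimes compared in
the experiments:

* :func:`train_nelder_mead` — derivative-free simplex search on the
  full-batch MSE (every objective evaluation measures every sample, so a
  step costs ``shots * n_samples`` measurements);
* :func:`train_sgd` — single-sample stochastic gradient descent with Adam,
  where the gradient of ``B`` comes from the parameter-shift rule
  ``dB/dtheta_k = (B(theta_k + pi/2) - B(theta_k - pi/2)) / 2`` (exact for
  Pauli-rotation angles) and the loss chain rule contributes
  ``dL/dB = -2 (y - B)``.  A step costs ``shots + 2 * shots * n_params``
  measurements: one forward evaluation plus two shifted evaluations per
  trainable angle.

Learning-curve R² is always evaluated with EXACT readout at the current
parameters, regardless of the shot count used for training, so that curves
at different shot budgets are comparable.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .circuits import (
    EncodingSpec,
    ParameterizedCircuit,
    bind_parameters,
    encode_state,
    random_initial_theta,
    run_circuit,
)
from .simulator import (
    EXACT,
    StateVector,
    z_expectation_exact,
    z_expectation_sampled,
)

__all__ = [
    "EXACT",
    "LossSpec",
    "ShotBudget",
    "TrainingTrace",
    "EncodedDataset",
    "AdamState",
    "predict_one",
    "ansatz_expectation",
    "mse_loss",
    "parameter_shift_gradient",
    "finite_difference_gradient",
    "adam_step",
    "train_sgd",
    "train_nelder_mead",
    "shots_per_step",
]

FULL = "full"
SINGLE_RANDOM = "single_random"


@dataclass(frozen=True)
class LossSpec:
    """MSE objective configuration: shot count and batch mode."""

    shots: int | str = EXACT
    batch: str = FULL

    def __post_init__(self) -> None:
        _check_shots(self.shots)
        if self.batch not in (FULL, SINGLE_RANDOM):
            raise ValueError(f"unknown batch mode {self.batch!r}")


@dataclass(frozen=True)
class ShotBudget:
    """Measurement-budget bookkeeping for one optimization step."""

    shots_per_expectation: int
    n_samples: int
    n_trainable: int

    def __post_init__(self) -> None:
        if min(self.shots_per_expectation, self.n_samples, self.n_trainable) < 1:
            raise ValueError("all ShotBudget fields must be positive")


def shots_per_step(budget: ShotBudget, method: str) -> int:
    """Total measurements per optimization step for each training regime.

    ``"nelder_mead"``: one full-batch loss evaluation = shots x n_samples.
    ``"sgd_param_shift"``: one forward + two shifted evaluations per
    trainable angle on a single sample = shots + 2 x shots x n_trainable.
    """
    if method == "nelder_mead":
        return budget.shots_per_expectation * budget.n_samples
    if method == "sgd_param_shift":
        return budget.shots_per_expectation * (1 + 2 * budget.n_trainable)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class TrainingTrace:
    """Per-step training record: loss, exact-readout R², theta, shot budget."""

    optimizer: str
    seed: int
    steps: list[int] = field(default_factory=list)
    sample_indices: list[int | str] = field(default_factory=list)
    losses: list[float] = field(default_factory=list)
    r2s: list[float] = field(default_factory=list)
    thetas: list[np.ndarray] = field(default_factory=list)
    cum_shots: list[int] = field(default_factory=list)

    def append(self, step, sample, loss, r2, theta, cum) -> None:
        if self.cum_shots and cum < self.cum_shots[-1]:
            raise ValueError("cumulative shots must be non-decreasing")
        self.steps.append(int(step))
        self.sample_indices.append(sample)
        self.losses.append(float(loss))
        self.r2s.append(float(r2))
        self.thetas.append(np.asarray(theta, dtype=float).copy())
        self.cum_shots.append(int(cum))

    def __len__(self) -> int:
        return len(self.steps)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.steps,
                "sample": [str(s) for s in self.sample_indices],
                "loss": self.losses,
                "r2": self.r2s,
                "cum_shots": self.cum_shots,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _check_shots(shots) -> None:
    if shots == EXACT:
        return
    if not isinstance(shots, (int, np.integer)) or shots < 1:
        raise ValueError(f"shots must be a positive integer or EXACT, got {shots!r}")


def _readout(state: StateVector, qubit: int, shots, rng) -> float:
    if shots == EXACT:
        return z_expectation_exact(state, qubit).value
    if rng is None:
        raise ValueError("finite-shot readout needs an explicit rng")
    return z_expectation_sampled(state, qubit, int(shots), rng).value


@lru_cache(maxsize=None)
def _index_pairs(n_qubits: int, qubit: int) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(2**n_qubits)
    i0 = idx[(idx >> qubit) & 1 == 0]
    return i0, i0 | (1 << qubit)


@lru_cache(maxsize=None)
def _cnot_perm(n_qubits: int, control: int, target: int) -> np.ndarray:
    idx = np.arange(2**n_qubits)
    return np.where((idx >> control) & 1 == 1, idx ^ (1 << target), idx)


def _u3_entries(theta: float, phi: float, lam: float):
    # closed form of RZ(phi) @ RY(theta) @ RZ(lam)
    c, s = math.cos(theta / 2.0), math.sin(theta / 2.0)
    return (
        c * cmath.exp(-0.5j * (phi + lam)),
        -s * cmath.exp(-0.5j * (phi - lam)),
        s * cmath.exp(0.5j * (phi - lam)),
        c * cmath.exp(0.5j * (phi + lam)),
    )


class _CompiledAnsatz:
    """Flattened gate program for fast repeated evaluation at varying theta.

    Numerically independent of the generic gate path: single-qubit matrices
    use closed-form entries instead of composed 2x2 matmuls, so agreement
    with bind_parameters + run_circuit is a meaningful cross-check.
    """

    __slots__ = ("n_qubits", "readout_qubit", "n_trainable", "_ops", "_p0_mask")

    def __init__(self, circuit: ParameterizedCircuit):
        self.n_qubits = circuit.n_qubits
        self.readout_qubit = circuit.readout_qubit
        self.n_trainable = circuit.n_trainable
        slot_of = {slot: k for k, slot in enumerate(circuit.trainable_slots)}
        self._ops = []
        for gi, g in enumerate(circuit.gates):
            if g.kind == "CNOT":
                self._ops.append(("cnot", _cnot_perm(self.n_qubits, g.control, g.target)))
            else:
                slots = tuple(slot_of.get((gi, ai)) for ai in range(len(g.angles)))
                pairs = _index_pairs(self.n_qubits, g.target)
                self._ops.append((g.kind, g.angles, slots, pairs))
        idx = np.arange(2**self.n_qubits)
        self._p0_mask = (idx >> self.readout_qubit) & 1 == 0

    def _angles(self, base, slots, theta):
        return [theta[s] if s is not None else a for a, s in zip(base, slots)]

    def prob_zero(self, amps: np.ndarray, theta: np.ndarray) -> float:
        for op in self._ops:
            if op[0] == "cnot":
                amps = amps[op[1]]
                continue
            kind, base, slots, (i0, i1) = op
            a = self._angles(base, slots, theta)
            a0, a1 = amps[i0], amps[i1]
            out = np.empty_like(amps)
            if kind == "RY":
                c, s = math.cos(a[0] / 2.0), math.sin(a[0] / 2.0)
                out[i0] = c * a0 - s * a1
                out[i1] = s * a0 + c * a1
            elif kind == "RZ":
                e = cmath.exp(-0.5j * a[0])
                out[i0] = e * a0
                out[i1] = a1 * e.conjugate()
            else:  # U3
                m00, m01, m10, m11 = _u3_entries(*a)
                out[i0] = m00 * a0 + m01 * a1
                out[i1] = m10 * a0 + m11 * a1
            amps = out
        p0 = float(np.sum(np.abs(amps[self._p0_mask]) ** 2))
        return min(max(p0, 0.0), 1.0)


@lru_cache(maxsize=128)
def _compile_ansatz(circuit: ParameterizedCircuit) -> _CompiledAnsatz:
    return _CompiledAnsatz(circuit)


def ansatz_expectation(
    state: StateVector,
    ansatz: ParameterizedCircuit,
    theta: np.ndarray,
    shots=EXACT,
    rng: np.random.Generator | None = None,
) -> float:
    """Z expectation on the readout qubit after applying ansatz(theta) to state."""
    _check_shots(shots)
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (ansatz.n_trainable,):
        raise ValueError(
            f"expected {ansatz.n_trainable} parameters, got shape {theta.shape}"
        )
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite parameter value")
    p0 = _compile_ansatz(ansatz).prob_zero(state.amplitudes, theta)
    if shots == EXACT:
        return 2.0 * p0 - 1.0
    if rng is None:
        raise ValueError("finite-shot readout needs an explicit rng")
    shots = int(shots)
    n_zero = int(rng.binomial(shots, p0))
    return (2.0 * n_zero - shots) / shots


def predict_one(
    x_scaled: np.ndarray,
    theta: np.ndarray,
    ansatz: ParameterizedCircuit,
    spec: EncodingSpec | None = None,
    shots=EXACT,
    rng: np.random.Generator | None = None,
) -> float:
    """Model output in [-1, 1] for one scaled sample."""
    return ansatz_expectation(encode_state(x_scaled, spec), ansatz, theta, shots, rng)


class EncodedDataset:
    """A preprocessed dataset with encoder output states cached per sample.

    The encoder is fixed given x, so its output state is computed once per
    sample; training then only applies the (re-bound) ansatz.
    """

    def __init__(self, X_scaled: np.ndarray, y_scaled: np.ndarray, spec: EncodingSpec | None = None):
        X_scaled = np.asarray(X_scaled, dtype=float)
        self.y = np.asarray(y_scaled, dtype=float)
        if X_scaled.ndim != 2 or X_scaled.shape[0] != self.y.shape[0]:
            raise ValueError("X_scaled must be 2-D with one row per target")
        if X_scaled.shape[0] == 0:
            raise ValueError("dataset is empty")
        self.spec = spec or EncodingSpec(n_qubits=X_scaled.shape[1])
        self.states = [encode_state(x, self.spec) for x in X_scaled]

    def __len__(self) -> int:
        return len(self.states)

    def predictions(
        self, ansatz, theta, shots=EXACT, rng=None
    ) -> np.ndarray:
        return np.array(
            [ansatz_expectation(s, ansatz, theta, shots, rng) for s in self.states]
        )

    def exact_r2(self, ansatz, theta) -> float:
        """Training R² (scaled-target scale) with exact readout."""
        pred = self.predictions(ansatz, theta, EXACT)
        ss_tot = float(np.sum((self.y - self.y.mean()) ** 2))
        if ss_tot == 0.0:
            raise ValueError("target variance is zero; R2 undefined")
        return 1.0 - float(np.sum((self.y - pred) ** 2)) / ss_tot


def mse_loss(
    theta: np.ndarray,
    encoded: EncodedDataset,
    ansatz: ParameterizedCircuit,
    loss_spec: LossSpec = LossSpec(),
    rng: np.random.Generator | None = None,
) -> float:
    """Mean squared error over the batch (full, or one random sample)."""
    if len(encoded) == 0:
        raise ValueError("empty batch")
    if loss_spec.batch == SINGLE_RANDOM:
        if rng is None:
            raise ValueError("single-sample batch needs an rng to draw the sample")
        idx = [int(rng.integers(len(encoded)))]
    else:
        idx = list(range(len(encoded)))
    err = 0.0
    for i in idx:
        b = ansatz_expectation(encoded.states[i], ansatz, theta, loss_spec.shots, rng)
        err += (encoded.y[i] - b) ** 2
    return err / len(idx)


def parameter_shift_gradient(
    theta: np.ndarray,
    ansatz: ParameterizedCircuit,
    state: StateVector,
    shots=EXACT,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """dB/dtheta by the parameter-shift rule, component by component.

    Every trainable angle is a Pauli-rotation angle (U3 decomposes into
    RZ·RY·RZ), so the +-pi/2 shift formula is exact; with EXACT readout the
    result equals the analytic gradient.
    """
    theta = np.asarray(theta, dtype=float)
    grad = np.empty_like(theta)
    shift = np.zeros_like(theta)
    for k in range(theta.size):
        shift[k] = 0.5 * math.pi
        b_plus = ansatz_expectation(state, ansatz, theta + shift, shots, rng)
        b_minus = ansatz_expectation(state, ansatz, theta - shift, shots, rng)
        shift[k] = 0.0
        grad[k] = 0.5 * (b_plus - b_minus)
    return grad


def finite_difference_gradient(
    theta: np.ndarray,
    ansatz: ParameterizedCircuit,
    state: StateVector,
    h: float = 1e-6,
) -> np.ndarray:
    """Central-difference dB/dtheta with exact readout (oracle for tests)."""
    if h <= 0:
        raise ValueError("finite-difference step h must be positive")
    theta = np.asarray(theta, dtype=float)
    grad = np.empty_like(theta)
    shift = np.zeros_like(theta)
    for k in range(theta.size):
        shift[k] = h
        b_plus = ansatz_expectation(state, ansatz, theta + shift, EXACT)
        b_minus = ansatz_expectation(state, ansatz, theta - shift, EXACT)
        shift[k] = 0.0
        grad[k] = (b_plus - b_minus) / (2.0 * h)
    return grad


@dataclass
class AdamState:
    """First/second moment accumulators for Adam."""

    m: np.ndarray
    v: np.ndarray
    t: int = 0

    @classmethod
    def zeros(cls, n: int) -> "AdamState":
        return cls(m=np.zeros(n), v=np.zeros(n), t=0)


def adam_step(
    theta: np.ndarray,
    grad: np.ndarray,
    state: AdamState,
    lr: float = 0.03,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
) -> tuple[np.ndarray, AdamState]:
    """One bias-corrected Adam update; aborts on a non-finite gradient."""
    grad = np.asarray(grad, dtype=float)
    if grad.shape != np.shape(theta):
        raise ValueError("theta and gradient shapes differ")
    if not np.all(np.isfinite(grad)):
        raise FloatingPointError(f"non-finite gradient: {grad}")
    t = state.t + 1
    m = beta1 * state.m + (1.0 - beta1) * grad
    v = beta2 * state.v + (1.0 - beta2) * grad**2
    m_hat = m / (1.0 - beta1**t)
    v_hat = v / (1.0 - beta2**t)
    theta_new = theta - lr * m_hat / (np.sqrt(v_hat) + eps)
    return theta_new, AdamState(m=m, v=v, t=t)


def train_sgd(
    encoded: EncodedDataset,
    ansatz: ParameterizedCircuit,
    shots=EXACT,
    n_steps: int = 300,
    seed: int = 0,
    lr: float = 0.03,
    theta0: np.ndarray | None = None,
    eval_r2_every: int = 1,
) -> tuple[np.ndarray, TrainingTrace]:
    """Single-sample SGD with Adam and parameter-shift gradients.

    Each step draws one sample uniformly (with replacement), measures
    ``B`` once and the 2 x n_params shifted expectations, and applies the
    chain rule ``dL/dtheta = -2 (y - B) dB/dtheta``.  R² over the full
    training set (exact readout) is recorded every ``eval_r2_every`` steps
    and carried forward in between.
    """
    _check_shots(shots)
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if eval_r2_every < 1:
        raise ValueError("eval_r2_every must be >= 1")
    rng = np.random.default_rng(seed)
    theta = (
        np.asarray(theta0, dtype=float)
        if theta0 is not None
        else random_initial_theta(ansatz, rng)
    )
    if theta.shape != (ansatz.n_trainable,):
        raise ValueError("theta0 length does not match the ansatz")
    adam = AdamState.zeros(theta.size)
    trace = TrainingTrace(optimizer="sgd_param_shift", seed=seed)
    if shots == EXACT:
        step_shots = 0
    else:
        step_shots = shots_per_step(
            ShotBudget(int(shots), len(encoded), ansatz.n_trainable), "sgd_param_shift"
        )
    cum = 0
    r2 = math.nan
    for step in range(n_steps):
        i = int(rng.integers(len(encoded)))
        b = ansatz_expectation(encoded.states[i], ansatz, theta, shots, rng)
        db = parameter_shift_gradient(theta, ansatz, encoded.states[i], shots, rng)
        residual = encoded.y[i] - b
        grad = -2.0 * residual * db
        theta, adam = adam_step(theta, grad, adam, lr=lr)
        cum += step_shots
        if step % eval_r2_every == 0 or step == n_steps - 1:
            r2 = encoded.exact_r2(ansatz, theta)
        trace.append(step, i, residual**2, r2, theta, cum)
    return theta, trace


def train_nelder_mead(
    encoded: EncodedDataset,
    ansatz: ParameterizedCircuit,
    shots=EXACT,
    max_fev: int = 2000,
    seed: int = 0,
    theta0: np.ndarray | None = None,
    eval_r2_every: int = 1,
    xatol: float = 1e-4,
    fatol: float = 1e-4,
) -> tuple[np.ndarray, TrainingTrace]:
    """Nelder–Mead simplex search on the full-batch MSE.

    One "optimization step" is one objective evaluation (a full pass over
    the training samples), matching the measurement-budget accounting of
    ``shots_per_step(..., "nelder_mead")``.
    """
    _check_shots(shots)
    if max_fev < 1:
        raise ValueError("max_fev must be >= 1")
    rng = np.random.default_rng(seed)
    theta_init = (
        np.asarray(theta0, dtype=float)
        if theta0 is not None
        else random_initial_theta(ansatz, rng)
    )
    if theta_init.shape != (ansatz.n_trainable,):
        raise ValueError("theta0 length does not match the ansatz")
    spec = LossSpec(shots=shots, batch=FULL)
    step_shots = (
        0
        if shots == EXACT
        else shots_per_step(
            ShotBudget(int(shots), len(encoded), ansatz.n_trainable), "nelder_mead"
        )
    )
    trace = TrainingTrace(optimizer="nelder_mead", seed=seed)
    counter = {"n": 0, "cum": 0, "r2": math.nan}

    def objective(theta: np.ndarray) -> float:
        loss = mse_loss(theta, encoded, ansatz, spec, rng)
        if not math.isfinite(loss):
            raise FloatingPointError(f"non-finite Nelder-Mead loss: {loss}")
        counter["cum"] += step_shots
        if counter["n"] % eval_r2_every == 0:
            counter["r2"] = encoded.exact_r2(ansatz, theta)
        trace.append(counter["n"], FULL, loss, counter["r2"], theta, counter["cum"])
        counter["n"] += 1
        return loss

    res = minimize(
        objective,
        theta_init,
        method="Nelder-Mead",
        options={
            "maxfev": max_fev,
            "xatol": xatol,
            "fatol": fatol,
            "adaptive": False,
        },
    )
    return np.asarray(res.x, dtype=float), trace
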