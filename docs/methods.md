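# Methods

## Model

The regression model is a parameterized quantum circuit on `n = 4` qubits.
For a preprocessed descriptor vector `x ∈ [−π, π]^4` and parameter vector
`θ`, the prediction is

    f_θ(x) = ⟨Z_r⟩  of  U_ansatz(θ) · U_enc(x) |0000⟩,

the Pauli-Z expectation of the readout qubit `r`. Because `⟨Z⟩ ∈ [−1, 1]`,
the target is squashed into that interval before training (see
Preprocessing). The mean squared error between the squashed target and
`f_θ(x)` is the training objective.

### Gate conventions

Half-angle conventions throughout: `RY(t) = exp(−i t Y/2)`,
`RZ(t) = exp(−i t Z/2)`, and `U3(θ, φ, λ) = RZ(φ)·RY(θ)·RZ(λ)` up to global
phase, so `⟨Z⟩ = cos t` after `RY(t)|0⟩`. Qubits are little-endian: bit `k`
of a basis-state index is qubit `k`, qubit 0 is the top wire. These choices
fix the numerical values of trained parameters; only behaviors, not
absolute parameter values, are portable across simulators with other
conventions.

### Encoder

Per repetition (2 by default): `RY(x_i)` then `RZ(x_i)` on each qubit `i`,
followed by a CNOT chain `0→1→2→3` (a ring closure is available via
`EncodingSpec.entangler`). The scaled component value is used as the angle
directly — the min–max scaling to `[−π, π]` is what makes it an angle. The
encoder carries no trainable parameters, so its output state is cached per
sample during training (`EncodedDataset`).

### Ansätze

**Layered** (`build_original_ansatz`): `L` layers of CNOT chain + one `U3`
per qubit → `3·4·L` trainable angles; readout on the last wire, which is
where the entangling chain accumulates.

**MERA** (`build_mera_ansatz`): four two-qubit blocks — disentangler on
wires (1,2), isometries on (0,1) and (3,2), top block on (1,2) — each a
`U3` on both wires followed by a CNOT, giving 8 `U3` = 24 parameters, the
same count as the layered circuit at `L = 2`; readout on wire 2. The CNOT
of each isometry *targets* the wire kept by the next level: a CNOT never
changes the Z marginal of its own control, so orienting the CNOTs toward
the readout is what places every block inside the readout's causal cone.
Four of the 24 parameters are still structurally redundant — the leftmost
`RZ(φ)` of a `U3` on a wire used only as a CNOT control afterwards commutes
with the (diagonal-on-that-wire) backpropagated observable. This redundancy
is inherent to the per-wire `U3` parameterization and is left in place to
keep the printed parameter count (24).

## Readout and shot noise

Exact readout computes `P(qubit = 0)` from the amplitudes. Finite-shot
readout draws `n_zero ~ Binomial(shots, P)` and returns
`(2·n_zero − shots)/shots` — an unbiased estimator of `⟨Z⟩` with standard
error `2·sqrt(P(1−P)/shots)`. No other hardware noise (decoherence, gate
error, crosstalk) is modelled. All randomness flows through explicit
`numpy.random.Generator` objects; there is no global state.

## Training

**Nelder–Mead** (`scipy.optimize.minimize`) searches the full-batch MSE.
One "step" is one objective evaluation: every sample's expectation must be
measured, costing `shots × n_samples` measurements (860,000 at 10,000
shots × 86 samples). Stopping: simplex tolerances `xatol = fatol = 1e-4`
or the evaluation budget, whichever first.

**SGD + parameter-shift**: each step draws one sample uniformly with
replacement, measures its forward expectation `B` and the two shifted
expectations per trainable angle, and applies Adam to
`∇L = −2(y − B)·dB/dθ` with `dB/dθ_k = ½[B(θ_k+π/2) − B(θ_k−π/2)]`. The
shift rule is exact for Pauli-rotation generators, which every slot is
because `U3` decomposes into `RZ·RY·RZ`. Cost per step:
`shots·(1 + 2·n_params)` (4,900 at 100 shots, 24 parameters). With exact
readout the parameter-shift gradient equals the analytic gradient to
numerical precision (checked against central finite differences at
`h = 1e-6`).

Adam uses the standard bias-corrected update with `β₁ = 0.9, β₂ = 0.999,
ε = 1e-8` and default step size `α = 0.03`, chosen by a calibration sweep
on exact-readout runs (larger steps oscillate, smaller ones stall within
a few hundred steps); `α` is exposed in every config. Initial angles are
i.i.d. uniform on `[0, 2π)` under the run seed. A non-finite loss or
gradient aborts the run with the trace preserved.

**Learning-curve protocol.** The per-step R² recorded in `TrainingTrace`
is always evaluated with *exact* readout at the current parameters,
whatever the training shot count — otherwise curves at different budgets
would not be comparable. Because `TrainingTrace` stores R² on the squashed
target scale while the pipeline reports property units, the two differ
slightly (the inverse transform is monotone but nonlinear). Cumulative
shots in the trace count only training measurements, not this evaluation.

**Budget matching.** When SGD and Nelder–Mead are compared at the same
shot setting, Nelder–Mead receives
`⌊steps_SGD · cost_SGD / cost_NM⌋` objective evaluations so both consume
the same total measurement budget.

## Preprocessing and metrics

PCA (scikit-learn) reduces the descriptors to 4 components — one per
qubit; zero-variance columns are dropped first with a warning. Each
retained component is min–max scaled to exactly `[−π, π]` independently;
the target is min–max scaled to `[−1, 1]` then passed through `tanh`, so
the training range becomes `[−tanh 1, tanh 1] ≈ [−0.76, 0.76]`. The
headroom left inside `[−1, 1]` is deliberate: a model squashed to the
training extremes could never predict beyond them. The inverse map is
`minmax⁻¹(atanh(·))` with clipping at `±(1 − 1e-9)` (warned) so
saturated predictions stay finite.

R² = 1 − Σ(y − y_calc)² / Σ(y − ȳ)² on in-sample calculated values;
Q² is the same functional on pooled out-of-fold predictions from k-fold
cross-validation (k = 10 by default, shuffled folds under a recorded
seed). Both are computed in property units. Inside each CV fold the whole
preprocessor (PCA rotation, min–max ranges, target squash) is re-fitted on
that fold's training rows only; test-fold descriptors may then map outside
`[−π, π]` and are clipped to the valid encoding range. Q² is therefore
fold-seed dependent, as it is in any shuffled CV.

## Synthetic data

The generator stands in for a proprietary monomer/polymer descriptor
table and reproduces its statistical shape rather than its chemistry:
`X = Z·W + ε` with `Z` an `n × 4` Gaussian latent matrix (variances
1.0, 0.6, 0.35, 0.2 — strictly decreasing, as PCA spectra of correlated
descriptor tables are), `W` a random orthonormal-row mixing into 10
descriptors, and isotropic noise `ε` sized so the top-4 principal
components carry 99.5% of the variance in expectation (matching the
">99%" compressibility of real descriptor tables). The default target is
`y = Σ a_k sin(z_k) + N(0, 0.05²)` with `a = (1.0, 0.8, 0.6, 0.4)` — smooth,
nonlinear, bounded, and spanning most of the squashed range; `linear` and
`interaction` (`z₁z₂ + sin z₃ + z₄²`) targets are also registered.
Defaults (86 samples, 10 descriptors) mirror the study shapes.

What the generator does **not** emulate: chemically meaningful descriptor
semantics, heavy-tailed or discrete descriptors, heteroscedastic noise,
and the unknown true difficulty of the descriptor→T_g map. Absolute R²/Q²
values on synthetic data are therefore not comparable to values reported
on any real dataset; qualitative orderings (deeper layered circuits fit
better; MERA beats the layered circuit at 24 parameters; SGD +
parameter-shift tolerates small shot counts where Nelder–Mead fails) are
the transferable results, and they are asserted on medians over ≥ 5 seeds
because single runs depend visibly on the random initial angles.

## Problem sizes

The experiment drivers default to sizes that keep a full run on one CPU
in the order of a minute: 400–500 SGD steps, 5 seeds per sweep point,
layer sweeps over L ∈ {1, 2, 4} (plus L = 3 in tests), shot sweeps over
{100, 1,000, 10,000} with a 200-step SGD reference. Exact-readout runs of
the 4-qubit circuits evaluate ~10⁴ circuit executions per second, so
deeper sweeps (L up to 8, more seeds) scale linearly if wanted.

## Numerical choices and degenerate inputs

- State norm is re-validated after every gate (tolerance 1e-8 on
  construction; unitarity holds to ~1e-15 per gate).
- A hot-path evaluator (`_CompiledAnsatz`) applies closed-form 2×2 gate
  entries to cached encoder states; it is checked in the tests against the
  generic bind-and-run gate path, which composes matrices differently.
- Zero target variance raises (R² undefined); constant descriptor columns
  are dropped with a warning; a degenerate principal component (zero
  range) raises rather than dividing by zero.
- `shots` is either a positive integer or the `EXACT` sentinel; exact runs
  record zero cumulative shots.
- Nelder–Mead on a sampled (noisy) objective is allowed to terminate early
  on its simplex tolerance; the trace keeps every evaluation either way.

## Known limitations

- 4-qubit dense simulation only; no density matrices, no hardware noise
  channels beyond finite sampling, no transpilation.
- Single-sample SGD with a constant step does not converge to a point —
  the final iterate oscillates around the optimum, so end-of-run R² is a
  noisy summary; the learning curve (and its best attained value) is the
  more stable readout. Learning-rate schedules and mini-batches are out of
  scope by design.
- The layered/MERA wiring follows the canonical textbook layouts; other
  entangling topologies are configurable but unexplored.
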