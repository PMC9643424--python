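"""End-to-end QSPR regression with a quantum-circuit model.

The pipeline follows the usual QCL recipe for descriptor tables:

1. PCA compresses the ``d`` descriptors to a few components (default 4,
   one per qubit) — collinear descriptor tables lose almost nothing.
2. Each retained component is min–max scaled to ``[-pi, pi]`` so the value
   itself is a Bloch-sphere rotation angle.
3. The target is min–max scaled to ``[-1, 1]`` and squashed through tanh,
   landing the training range on ``[-tanh 1, tanh 1] = [-0.76, 0.76]``;
   keeping headroom inside the circuit's ``[-1, 1]`` output range lets the
   model express targets beyond the training extremes.
4. A variational circuit is trained on the scaled data; predictions are
   mapped back to property units through the clipped inverse transform
   ``minmax^-1(atanh(.))``.

Model quality is reported as the coefficient of determination R² on
in-sample calculated values, and Q² on pooled out-of-fold predictions from
k-fold cross-validation (both computed in property units).  Scalers and the
PCA rotation are re-fitted inside every CV fold from that fold's training
rows only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold

from .circuits import (
    EncodingSpec,
    ParameterizedCircuit,
    build_mera_ansatz,
    build_original_ansatz,
    encode_state,
)
from .simulator import EXACT
from .training import (
    EncodedDataset,
    TrainingTrace,
    ansatz_expectation,
    train_nelder_mead,
    train_sgd,
)

__all__ = [
    "QSPRDataset",
    "FittedPreprocessor",
    "ModelConfig",
    "TrainedModel",
    "CVResult",
    "fit_preprocessor",
    "r_squared",
    "q_squared_cv",
    "cross_validate",
    "build_ansatz",
    "fit",
    "predict",
]

TANH1 = float(np.tanh(1.0))


@dataclass
class QSPRDataset:
    """Descriptor matrix X (n x d) and property vector y with provenance."""

    X: np.ndarray
    y: np.ndarray
    names: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float)
        n, d = self.X.shape
        if n < 2 or d < 1:
            raise ValueError("need at least 2 samples and 1 descriptor")
        if self.y.shape != (n,):
            raise ValueError("y length must match the number of rows of X")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("dataset contains missing or non-finite values")
        if self.names is not None and len(self.names) != d:
            raise ValueError("names length must match the number of descriptors")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.X.shape[1]

    def subset(self, rows) -> "QSPRDataset":
        return QSPRDataset(self.X[rows], self.y[rows], self.names, dict(self.meta))

    def to_csv(self, path, target: str = "target") -> None:
        names = self.names or [f"desc_{j}" for j in range(self.n_descriptors)]
        df = pd.DataFrame(self.X, columns=names)
        df[target] = self.y
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, target: str = "target") -> "QSPRDataset":
        df = pd.read_csv(path)
        if target not in df.columns:
            raise ValueError(f"target column {target!r} not found in {path}")
        y = df.pop(target).to_numpy(dtype=float)
        return cls(X=df.to_numpy(dtype=float), y=y, names=list(df.columns),
                   meta={"source": str(path)})


@dataclass
class FittedPreprocessor:
    """PCA rotation + per-component min–max to [-pi, pi] + tanh target squash."""

    mean_: np.ndarray
    components_: np.ndarray  # (n_components, d_kept)
    explained_variance_ratio_: np.ndarray
    kept_columns: np.ndarray
    x_min: np.ndarray
    x_max: np.ndarray
    y_min: float
    y_max: float

    @property
    def n_components(self) -> int:
        return self.components_.shape[0]

    @property
    def cumulative_explained_variance(self) -> float:
        return float(np.sum(self.explained_variance_ratio_[: self.n_components]))

    def transform_x(self, X: np.ndarray, clip: bool = True) -> np.ndarray:
        """Project onto the retained components and scale to [-pi, pi].

        New samples can fall outside the training range; with ``clip`` they
        are clamped to the valid encoding interval.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        T = (X[:, self.kept_columns] - self.mean_) @ self.components_.T
        span = self.x_max - self.x_min
        scaled = -np.pi + 2.0 * np.pi * (T - self.x_min) / span
        if clip:
            scaled = np.clip(scaled, -np.pi, np.pi)
        return scaled

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        u = -1.0 + 2.0 * (y - self.y_min) / (self.y_max - self.y_min)
        return np.tanh(u)

    def inverse_transform_y(self, y_scaled: np.ndarray) -> np.ndarray:
        """Map circuit outputs back to property units (clipped atanh)."""
        v = np.asarray(y_scaled, dtype=float)
        limit = 1.0 - 1e-9
        if np.any(np.abs(v) >= limit):
            warnings.warn(
                "prediction at or beyond the tanh saturation bound; clipping "
                "before atanh", RuntimeWarning, stacklevel=2,
            )
        u = np.arctanh(np.clip(v, -limit, limit))
        return self.y_min + (u + 1.0) / 2.0 * (self.y_max - self.y_min)

    def to_dict(self) -> dict:
        return {
            "mean": self.mean_.tolist(),
            "components": self.components_.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio_.tolist(),
            "kept_columns": self.kept_columns.tolist(),
            "x_min": self.x_min.tolist(),
            "x_max": self.x_max.tolist(),
            "y_min": self.y_min,
            "y_max": self.y_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedPreprocessor":
        return cls(
            mean_=np.asarray(d["mean"], dtype=float),
            components_=np.asarray(d["components"], dtype=float),
            explained_variance_ratio_=np.asarray(d["explained_variance_ratio"], dtype=float),
            kept_columns=np.asarray(d["kept_columns"], dtype=int),
            x_min=np.asarray(d["x_min"], dtype=float),
            x_max=np.asarray(d["x_max"], dtype=float),
            y_min=float(d["y_min"]),
            y_max=float(d["y_max"]),
        )


def fit_preprocessor(dataset: QSPRDataset, n_components: int = 4) -> FittedPreprocessor:
    """Fit PCA and min–max ranges on training data only.

    Constant descriptor columns carry no information and would destabilize
    the scaling; they are dropped with a warning.
    """
    X, y = dataset.X, dataset.y
    if n_components > dataset.n_descriptors:
        raise ValueError("n_components cannot exceed the number of descriptors")
    variances = X.var(axis=0)
    kept = np.flatnonzero(variances > 0)
    if kept.size < X.shape[1]:
        dropped = [i for i in range(X.shape[1]) if i not in kept]
        warnings.warn(
            f"dropping zero-variance descriptor column(s) {dropped}",
            RuntimeWarning, stacklevel=2,
        )
    if kept.size < n_components:
        raise ValueError("not enough informative descriptors for the requested PCA")
    pca = PCA(n_components=n_components)
    T = pca.fit_transform(X[:, kept])
    x_min, x_max = T.min(axis=0), T.max(axis=0)
    if np.any(x_max - x_min <= 0):
        raise ValueError("degenerate principal component (zero range)")
    y_min, y_max = float(y.min()), float(y.max())
    if y_max - y_min <= 0:
        raise ValueError("target has zero range; nothing to regress")
    return FittedPreprocessor(
        mean_=pca.mean_,
        components_=pca.components_,
        explained_variance_ratio_=pca.explained_variance_ratio_,
        kept_columns=kept,
        x_min=x_min,
        x_max=x_max,
        y_min=y_min,
        y_max=y_max,
    )


def r_squared(y: np.ndarray, y_calc: np.ndarray) -> float:
    """R² = 1 - sum((y - y_calc)^2) / sum((y - mean(y))^2)."""
    y = np.asarray(y, dtype=float)
    y_calc = np.asarray(y_calc, dtype=float)
    if y.shape != y_calc.shape:
        raise ValueError("y and y_calc lengths differ")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("target variance is zero; R2 undefined")
    return 1.0 - float(np.sum((y - y_calc) ** 2)) / ss_tot


@dataclass(frozen=True)
class ModelConfig:
    """Everything needed to reproduce a fit: circuit, optimizer, seeds."""

    ansatz: str = "mera"  # "original" | "mera"
    layers: int = 2  # layered-ansatz depth L (ignored for MERA)
    n_components: int = 4
    encoder_repetitions: int = 2
    entangler: str = "linear"
    optimizer: str = "sgd"  # "sgd" | "nelder_mead"
    shots: int | str = EXACT
    n_steps: int = 300  # SGD steps
    max_fev: int = 2000  # Nelder-Mead objective evaluations
    lr: float = 0.03
    seed: int = 0
    eval_r2_every: int = 1

    def __post_init__(self) -> None:
        if self.ansatz not in ("original", "mera"):
            raise ValueError(f"unknown ansatz {self.ansatz!r}")
        if self.optimizer not in ("sgd", "nelder_mead"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

    @property
    def encoding_spec(self) -> EncodingSpec:
        return EncodingSpec(
            n_qubits=self.n_components,
            repetitions=self.encoder_repetitions,
            entangler=self.entangler,
        )


def build_ansatz(config: ModelConfig) -> ParameterizedCircuit:
    if config.ansatz == "mera":
        return build_mera_ansatz(config.n_components)
    return build_original_ansatz(config.n_components, config.layers, config.entangler)


@dataclass
class TrainedModel:
    """Optimized parameters plus the fitted transforms and circuit spec."""

    config: ModelConfig
    theta: np.ndarray
    preprocessor: FittedPreprocessor
    trace: TrainingTrace | None = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (build_ansatz(self.config).n_trainable,):
            raise ValueError("theta length does not match the configured ansatz")

    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "theta": self.theta.tolist(),
            "preprocessor": self.preprocessor.to_dict(),
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "TrainedModel":
        d = json.loads(Path(path).read_text())
        return cls(
            config=ModelConfig(**d["config"]),
            theta=np.asarray(d["theta"], dtype=float),
            preprocessor=FittedPreprocessor.from_dict(d["preprocessor"]),
        )


def _train(encoded: EncodedDataset, config: ModelConfig, ansatz, seed: int):
    if config.optimizer == "sgd":
        return train_sgd(
            encoded, ansatz, shots=config.shots, n_steps=config.n_steps,
            seed=seed, lr=config.lr, eval_r2_every=config.eval_r2_every,
        )
    return train_nelder_mead(
        encoded, ansatz, shots=config.shots, max_fev=config.max_fev,
        seed=seed, eval_r2_every=config.eval_r2_every,
    )


def fit(dataset: QSPRDataset, config: ModelConfig | None = None) -> TrainedModel:
    """Preprocess, train and package a model on the full dataset."""
    config = config or ModelConfig()
    pre = fit_preprocessor(dataset, config.n_components)
    Xs = pre.transform_x(dataset.X)
    ys = pre.transform_y(dataset.y)
    ansatz = build_ansatz(config)
    encoded = EncodedDataset(Xs, ys, config.encoding_spec)
    theta, trace = _train(encoded, config, ansatz, config.seed)
    return TrainedModel(config=config, theta=theta, preprocessor=pre, trace=trace)


def predict(
    model: TrainedModel,
    X_new: np.ndarray,
    shots=EXACT,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Predict properties (original units) for new descriptor rows."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] <= int(model.preprocessor.kept_columns.max()):
        raise ValueError("X_new has fewer descriptors than the model expects")
    ansatz = build_ansatz(model.config)
    spec = model.config.encoding_spec
    Xs = model.preprocessor.transform_x(X_new)
    preds = np.array(
        [
            ansatz_expectation(encode_state(x, spec), ansatz, model.theta, shots, rng)
            for x in Xs
        ]
    )
    return model.preprocessor.inverse_transform_y(preds)


@dataclass
class CVResult:
    """Pooled out-of-fold predictions and the resulting Q²."""

    q2: float
    y_pred: np.ndarray
    fold_ids: np.ndarray
    models: list[TrainedModel] = field(default_factory=list)


def cross_validate(
    dataset: QSPRDataset,
    config: ModelConfig | None = None,
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """k-fold CV with per-fold preprocessing (no train/test leakage).

    Q² = 1 - sum((y - y_pred)^2) / sum((y - mean(y))^2) over the pooled
    out-of-fold predictions, in property units.
    """
    config = config or ModelConfig()
    if k > dataset.n_samples:
        raise ValueError("k cannot exceed the number of samples")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    y_pred = np.empty(dataset.n_samples)
    fold_ids = np.empty(dataset.n_samples, dtype=int)
    models: list[TrainedModel] = []
    for fold, (train_idx, test_idx) in enumerate(kf.split(dataset.X)):
        fold_config = replace(config, seed=config.seed + fold)
        model = fit(dataset.subset(train_idx), fold_config)
        y_pred[test_idx] = predict(model, dataset.X[test_idx])
        fold_ids[test_idx] = fold
        models.append(model)
    q2 = r_squared(dataset.y, y_pred)
    return CVResult(q2=q2, y_pred=y_pred, fold_ids=fold_ids, models=models)


def q_squared_cv(
    dataset: QSPRDataset,
    config: ModelConfig | None = None,
    k: int = 10,
    seed: int = 0,
) -> float:
    """Q² from k-fold cross-validation (see :func:`cross_validate`)."""
    return cross_validate(dataset, config, k=k, seed=seed).q2
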