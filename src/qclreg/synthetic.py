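"""Synthetic QSPR-style datasets with a low-rank descriptor structure.

Real monomer-descriptor tables are strongly collinear: a handful of latent
structural factors (size, branching, polarity, ...) drive many published
descriptors at once, which is why a 10-descriptor table compresses to 4
principal components carrying >99% of the variance.  The generator
reproduces exactly that statistic: latent factors ``Z`` (n x k Gaussian,
decreasing variances) are mixed into ``d`` descriptors through a random
orthonormal-row matrix ``W``, plus a small isotropic descriptor noise whose
variance is solved from the requested top-k explained-variance share.  The
property is a smooth (optionally nonlinear) function of the latent factors
plus Gaussian noise.

Defaults mirror the shapes of the study data this stands in for: 86
samples, 10 descriptors, 4 latent factors, top-4 cumulative explained
variance about 99.5%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .pipeline import QSPRDataset

__all__ = ["GeneratorSpec", "generate", "builtin_target_fns", "write_dataset"]


def _linear(Z: np.ndarray) -> np.ndarray:
    c = np.array([1.0, 0.8, 0.6, 0.4])[: Z.shape[1]]
    return Z @ c


def _sin_sum(Z: np.ndarray) -> np.ndarray:
    a = np.array([1.0, 0.8, 0.6, 0.4])[: Z.shape[1]]
    return np.sin(Z) @ a


def _interaction(Z: np.ndarray) -> np.ndarray:
    # needs >= 4 latent factors: z1*z2 + sin(z3) + z4^2  (1-based factors)
    if Z.shape[1] < 4:
        raise ValueError("interaction target needs at least 4 latent factors")
    return Z[:, 0] * Z[:, 1] + np.sin(Z[:, 2]) + Z[:, 3] ** 2


def builtin_target_fns() -> dict:
    """Registry of latent-space target maps (smooth, bounded-scaled)."""
    return {"linear": _linear, "sin_sum": _sin_sum, "interaction": _interaction}


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the latent-factor QSPR generator."""

    n_samples: int = 86
    n_descriptors: int = 10
    n_latent: int = 4
    latent_variances: tuple[float, ...] = (1.0, 0.6, 0.35, 0.2)
    target_fn: str = "sin_sum"
    noise_sd: float = 0.05
    top_evr: float = 0.995  # expected explained-variance share of the top n_latent PCs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not 1 <= self.n_latent <= self.n_descriptors:
            raise ValueError("need 1 <= n_latent <= n_descriptors")
        lv = np.asarray(self.latent_variances, dtype=float)
        if lv.shape != (self.n_latent,):
            raise ValueError("latent_variances length must equal n_latent")
        if np.any(lv <= 0) or np.any(np.diff(lv) >= 0):
            raise ValueError("latent_variances must be positive and strictly decreasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 < self.top_evr < 1.0:
            raise ValueError(
                "top_evr must lie strictly between 0 and 1; the requested "
                "variance split is infeasible otherwise"
            )
        if self.target_fn not in builtin_target_fns():
            raise KeyError(f"unknown target_fn {self.target_fn!r}")


def generate(spec: GeneratorSpec | None = None) -> QSPRDataset:
    """Draw one dataset; fully reproducible from ``spec.seed``."""
    spec = spec or GeneratorSpec()
    rng = np.random.default_rng(spec.seed)
    lv = np.asarray(spec.latent_variances, dtype=float)
    Z = rng.standard_normal((spec.n_samples, spec.n_latent)) * np.sqrt(lv)

    # orthonormal rows: mixing preserves the latent variances in descriptor space
    G = rng.standard_normal((spec.n_descriptors, spec.n_latent))
    Q, _ = np.linalg.qr(G)
    W = Q[:, : spec.n_latent].T

    # isotropic descriptor noise sized so E[top-k EVR] = top_evr:
    #   evr = sum(lv) / (sum(lv) + d * sigma_x^2)
    total = float(lv.sum())
    sigma_x2 = total * (1.0 - spec.top_evr) / (spec.top_evr * spec.n_descriptors)
    X = Z @ W + rng.standard_normal((spec.n_samples, spec.n_descriptors)) * np.sqrt(
        sigma_x2
    )

    y = builtin_target_fns()[spec.target_fn](Z)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=spec.n_samples)

    names = [f"desc_{j}" for j in range(spec.n_descriptors)]
    meta = {"generator": asdict(spec), "seed": spec.seed}
    meta["generator"]["latent_variances"] = list(spec.latent_variances)
    return QSPRDataset(X=X, y=np.asarray(y, dtype=float), names=names, meta=meta)


def write_dataset(dataset: QSPRDataset, csv_path, spec: GeneratorSpec | None = None) -> None:
    """Write the CSV plus a sidecar JSON recording the generating spec."""
    csv_path = Path(csv_path)
    dataset.to_csv(csv_path)
    sidecar = csv_path.with_suffix(".spec.json")
    payload = dataset.meta if spec is None else {"generator": asdict(spec), "seed": spec.seed}
    sidecar.write_text(json.dumps(payload, indent=2, default=list))
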