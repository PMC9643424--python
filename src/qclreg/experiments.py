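"""Scripted reproductions of the study designs on synthetic data.

Three experiment drivers, each writing a CSV table, a JSON manifest
(config + seeds + package version, enough to re-run bit-for-bit with exact
readout) and, when matplotlib is available, a PNG figure:

* :func:`run_layer_sweep` — training R² of the layered ansatz as depth L
  grows (exact readout, several seeds);
* :func:`run_shot_sweep` — learning curves of Nelder–Mead vs single-sample
  SGD with parameter-shift gradients across shot counts, under matched
  total measurement budgets, plus an exact-readout baseline;
* :func:`run_ansatz_compare` — layered (L=2) vs MERA at the same 24
  trainable parameters: in-sample R², cross-validated Q², and the
  actual-vs-estimated pairs behind them.

Comparative conclusions are drawn on medians over seeds; single runs
depend visibly on the random initial angles.
"""

from __future__ import annotations

import json
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .pipeline import (
    ModelConfig,
    QSPRDataset,
    build_ansatz,
    cross_validate,
    fit,
    fit_preprocessor,
    predict,
    r_squared,
)
from .simulator import EXACT
from .training import (
    EncodedDataset,
    ShotBudget,
    shots_per_step,
    train_nelder_mead,
    train_sgd,
)

__all__ = ["run_layer_sweep", "run_shot_sweep", "run_ansatz_compare"]


def _write_manifest(out_dir: Path, experiment: str, config: dict) -> None:
    manifest = {
        "experiment": experiment,
        "package_version": __version__,
        "config": config,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _maybe_plot(fig_fn, out_path: Path) -> None:
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return
    fig = fig_fn(plt)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def run_layer_sweep(
    dataset: QSPRDataset,
    layers: tuple[int, ...] = (1, 2, 4),
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
    n_steps: int = 400,
    out_dir: str | Path | None = None,
    lr: float = 0.03,
) -> pd.DataFrame:
    """Training R² of the layered ansatz per depth L (exact readout).

    A failed run is recorded with ``status="error"`` and the sweep
    continues.  Returns a tidy (L, seed, r2) table.
    """
    rows = []
    for L in layers:
        for seed in seeds:
            config = ModelConfig(
                ansatz="original", layers=L, optimizer="sgd", shots=EXACT,
                n_steps=n_steps, lr=lr, seed=seed, eval_r2_every=max(1, n_steps // 10),
            )
            try:
                model = fit(dataset, config)
                r2 = r_squared(dataset.y, predict(model, dataset.X))
                rows.append({"L": L, "seed": seed, "r2": r2, "status": "ok",
                             "n_params": build_ansatz(config).n_trainable})
            except Exception as exc:  # keep sweeping past a bad (L, seed) cell
                rows.append({"L": L, "seed": seed, "r2": np.nan,
                             "status": f"error: {exc}", "n_params": np.nan})
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "layer_sweep.csv", index=False)
        _write_manifest(out_dir, "layer_sweep", {
            "layers": list(layers), "seeds": list(seeds),
            "n_steps": n_steps, "lr": lr, "readout": "exact",
        })

        def _fig(plt):
            fig, ax = plt.subplots(figsize=(5, 3.5))
            med = table.groupby("L")["r2"].median()
            ax.plot(med.index, med.values, "o-")
            ax.set_xlabel("layers L")
            ax.set_ylabel("training $R^2$ (median over seeds)")
            return fig

        _maybe_plot(_fig, out_dir / "layer_sweep.png")
    return table


def run_shot_sweep(
    dataset: QSPRDataset,
    ansatz: str = "mera",
    shots_list: tuple[int, ...] = (100, 1000, 10000),
    optimizers: tuple[str, ...] = ("nelder_mead", "sgd"),
    sgd_steps: int = 200,
    seed: int = 0,
    out_dir: str | Path | None = None,
    lr: float = 0.03,
    eval_r2_every: int = 5,
) -> pd.DataFrame:
    """Learning curves per (optimizer, shots), budget-matched, plus EXACT baseline.

    Both optimizers start from the same random initial angles per shot
    setting.  Nelder–Mead is given the number of objective evaluations that
    matches the SGD run's total measurement count at the same shot setting.
    Per-step R² is always evaluated with exact readout.
    """
    config = ModelConfig(ansatz=ansatz, layers=2)
    circuit = build_ansatz(config)
    pre = fit_preprocessor(dataset, config.n_components)
    encoded = EncodedDataset(
        pre.transform_x(dataset.X), pre.transform_y(dataset.y), config.encoding_spec
    )
    rng = np.random.default_rng(seed)
    theta0 = rng.uniform(0.0, 2.0 * np.pi, size=circuit.n_trainable)

    frames = []

    def _collect(trace, optimizer, shots_label, per_step):
        df = trace.to_dataframe()
        df["optimizer"] = optimizer
        df["shots"] = shots_label
        df["shots_per_step"] = per_step
        frames.append(df)

    # exact-readout SGD baseline
    _, trace = train_sgd(encoded, circuit, shots=EXACT, n_steps=sgd_steps,
                         seed=seed, lr=lr, theta0=theta0, eval_r2_every=eval_r2_every)
    _collect(trace, "sgd", "exact", 0)

    for shots in shots_list:
        budget = ShotBudget(shots, len(encoded), circuit.n_trainable)
        sgd_step_cost = shots_per_step(budget, "sgd_param_shift")
        nm_step_cost = shots_per_step(budget, "nelder_mead")
        total_budget = sgd_steps * sgd_step_cost
        if "sgd" in optimizers:
            _, trace = train_sgd(
                encoded, circuit, shots=shots, n_steps=sgd_steps, seed=seed,
                lr=lr, theta0=theta0, eval_r2_every=eval_r2_every,
            )
            _collect(trace, "sgd", shots, sgd_step_cost)
        if "nelder_mead" in optimizers:
            nm_evals = max(2, total_budget // nm_step_cost)
            _, trace = train_nelder_mead(
                encoded, circuit, shots=shots, max_fev=nm_evals, seed=seed,
                theta0=theta0, eval_r2_every=eval_r2_every,
            )
            _collect(trace, "nelder_mead", shots, nm_step_cost)

    table = pd.concat(frames, ignore_index=True)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "shot_sweep.csv", index=False)
        _write_manifest(out_dir, "shot_sweep", {
            "ansatz": ansatz, "shots_list": list(shots_list),
            "optimizers": list(optimizers), "sgd_steps": sgd_steps,
            "seed": seed, "lr": lr, "r2_readout": "exact",
        })

        def _fig(plt):
            fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
            for ax, opt in zip(axes, ("nelder_mead", "sgd")):
                sub = table[table["optimizer"] == opt]
                for shots_label, grp in sub.groupby("shots"):
                    ax.plot(grp["step"], grp["r2"], label=f"shots={shots_label}")
                ax.set_title(opt)
                ax.set_xlabel("step")
                ax.legend(fontsize=7)
            axes[0].set_ylabel("$R^2$ (exact readout)")
            return fig

        _maybe_plot(_fig, out_dir / "shot_sweep.png")
    return table


def run_ansatz_compare(
    dataset: QSPRDataset,
    seeds: tuple[int, ...] = (0, 1, 2),
    n_steps: int = 300,
    k: int = 10,
    do_cv: bool = True,
    out_dir: str | Path | None = None,
    lr: float = 0.03,
) -> pd.DataFrame:
    """Layered L=2 vs MERA at equal parameter count (24), exact readout.

    Returns per-(arm, seed) metrics; per-sample (y, y_hat) pairs for both
    in-sample and CV predictions are written alongside when ``out_dir`` is
    given.  Seeds are shared across arms.
    """
    arms = {
        "original_l2": ModelConfig(ansatz="original", layers=2, optimizer="sgd",
                                   shots=EXACT, n_steps=n_steps, lr=lr),
        "mera": ModelConfig(ansatz="mera", optimizer="sgd", shots=EXACT,
                            n_steps=n_steps, lr=lr),
    }
    rows, pair_rows = [], []
    for arm, base_config in arms.items():
        n_params = build_ansatz(base_config).n_trainable
        for seed in seeds:
            config = replace(base_config, seed=seed,
                             eval_r2_every=max(1, n_steps // 10))
            model = fit(dataset, config)
            y_hat = predict(model, dataset.X)
            r2 = r_squared(dataset.y, y_hat)
            q2 = np.nan
            if do_cv:
                cv = cross_validate(dataset, config, k=k, seed=seed)
                q2 = cv.q2
                for i, (yi, yp) in enumerate(zip(dataset.y, cv.y_pred)):
                    pair_rows.append({"arm": arm, "seed": seed, "kind": "cv",
                                      "sample": i, "y": yi, "y_hat": yp})
            for i, (yi, yp) in enumerate(zip(dataset.y, y_hat)):
                pair_rows.append({"arm": arm, "seed": seed, "kind": "train",
                                  "sample": i, "y": yi, "y_hat": yp})
            rows.append({"arm": arm, "seed": seed, "n_params": n_params,
                         "r2": r2, "q2": q2})
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "ansatz_compare.csv", index=False)
        pd.DataFrame(pair_rows).to_csv(out_dir / "ansatz_compare_pairs.csv", index=False)
        _write_manifest(out_dir, "ansatz_compare", {
            "seeds": list(seeds), "n_steps": n_steps, "k": k, "do_cv": do_cv,
            "lr": lr, "readout": "exact",
        })

        def _fig(plt):
            fig, axes = plt.subplots(1, 2, figsize=(8, 3.5), sharex=True, sharey=True)
            pairs = pd.DataFrame(pair_rows)
            for ax, arm in zip(axes, arms):
                sub = pairs[(pairs["arm"] == arm) & (pairs["kind"] == "train")]
                ax.scatter(sub["y"], sub["y_hat"], s=8, alpha=0.6)
                lims = [pairs["y"].min(), pairs["y"].max()]
                ax.plot(lims, lims, "k--", lw=0.8)
                ax.set_title(arm)
                ax.set_xlabel("actual y")
            axes[0].set_ylabel("estimated y")
            return fig

        _maybe_plot(_fig, out_dir / "ansatz_compare.png")
    return table
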