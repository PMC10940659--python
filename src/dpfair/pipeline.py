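"""Experiment orchestration: generate → preprocess → calibrate → train over an
ε grid → evaluate → fairness audit → report.

``run_experiment`` executes every (ε, seed) cell of the grid, persists the
per-cell prediction tables as CSV, and aggregates utility and fairness
statistics across seeds.  ε = ∞ (``math.inf``) denotes the non-private mode
explicitly — it is never fed to the accountant.  Every number in the report
is recomputable from the persisted prediction tables alone.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .accounting import calibrate_sigma
from .evaluation import (
    PredictionTable,
    bootstrap,
    macro_auroc,
    metric_report,
    youden_threshold,
)
from .fairness import disparity_trend, fairness_report
from .models import ModelConfig
from .preprocessing import prepare_cxr_image, prepare_ct_volume
from .synthetic import (
    DatasetSpec,
    LabeledImageSet,
    cxr_desk_spec,
    generate_cxr_like,
    generate_ct_like,
    split_patientwise,
)
from .training import ArrayDataset, TrainConfig, train

logger = logging.getLogger("dpfair")

__all__ = [
    "ExperimentConfig",
    "prepare_dataset",
    "run_experiment",
    "report",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Full description of one privacy-grid experiment.

    ``epsilon_grid`` holds finite budgets sorted ascending; ``math.inf``
    entries mean non-private training.  Each (ε, seed) cell trains one model.
    """

    dataset_spec: DatasetSpec
    model: ModelConfig
    train_template: TrainConfig
    epsilon_grid: tuple[float, ...] = (0.5, 2.0, 8.0, math.inf)
    seeds: tuple[int, ...] = (0, 1, 2)
    split_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    delta: float | None = None  # default: 1 / n_records
    nonprivate_epochs: int | None = None
    nonprivate_learning_rate: float | None = None
    bootstrap_redraws: int = 1000
    train_extents: tuple[int, ...] | None = None  # resize step of preprocessing
    activation_dp: str = "mish"  # smoother activation for the private runs
    activation_nonprivate: str = "relu"
    output_dir: str = "results/experiment"

    def __post_init__(self) -> None:
        finite = [e for e in self.epsilon_grid if math.isfinite(e)]
        if not self.epsilon_grid:
            raise ValueError("epsilon grid must be non-empty")
        if any(e <= 0 for e in finite):
            raise ValueError("finite epsilons must be positive")
        if list(finite) != sorted(finite):
            raise ValueError("finite epsilons must be sorted ascending")
        if not self.seeds:
            raise ValueError("at least one seed required")


def prepare_dataset(
    ds: LabeledImageSet, target_extents: Sequence[int] | None = None
) -> ArrayDataset:
    """Preprocess a generated cohort into training tensors.

    Radiograph-style images go through resize → min-max → uint8 → histogram
    equalization and are rescaled to [-0.5, 0.5]; CT-style volumes are
    Hounsfield-windowed, resized and rescaled likewise.
    """
    meta = ds.metadata_frame()[["record_id", "patient_id", "sex", "age_group"]]
    labels = ds.binary_labels()
    if ds.kind == "cxr":
        imgs = np.stack(
            [prepare_cxr_image(r.image, target_extents) for r in ds.records]
        )
        x = imgs.astype(np.float64) / 255.0 - 0.5
    else:
        lo, hi = -150.0, 250.0
        vols = np.stack(
            [prepare_ct_volume(r.image, target_extents, lo=lo, hi=hi)
             for r in ds.records]
        )
        x = (vols - lo) / (hi - lo) - 0.5
    return ArrayDataset(x, labels, meta.reset_index(drop=True), ds.spec.labels)


def _epsilon_key(eps: float) -> str:
    return "inf" if math.isinf(eps) else f"{eps:g}"


def _train_counts(meta: pd.DataFrame) -> dict[str, dict[str, int]]:
    return {
        attr: meta[attr].astype(str).value_counts().to_dict()
        for attr in ("sex", "age_group")
    }


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run the full grid and return the aggregated report bundle.

    Per cell: calibrate σ (finite ε only), train, persist the prediction
    table, compute utility metrics per subgroup and the fairness report.
    Failures in one cell are logged and do not abort the others.  The bundle
    carries a manifest (seeds, σ values, spends, package versions) sufficient
    to reproduce any cell.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    spec = cfg.dataset_spec
    ds = (
        generate_cxr_like(spec)
        if len(spec.image_shape) == 2
        else generate_ct_like(spec)
    )
    logger.info("generated %d records in %.1fs", len(ds), time.time() - t0)
    train_set, val_set, test_set = split_patientwise(
        ds, cfg.split_fractions, seed=spec.seed
    )
    prep_train = prepare_dataset(train_set, cfg.train_extents)
    prep_test = prepare_dataset(test_set, cfg.train_extents)
    delta = cfg.delta if cfg.delta is not None else 1.0 / len(prep_train)
    reference_counts = _train_counts(prep_train.metadata)

    cells: dict[str, dict] = {}
    manifest = {
        "dpfair_version": __version__,
        "numpy_version": np.__version__,
        "n_records": {"train": len(prep_train), "val": len(val_set),
                      "test": len(prep_test)},
        "delta": delta,
        "seeds": list(cfg.seeds),
        "epsilon_grid": [_epsilon_key(e) for e in cfg.epsilon_grid],
        "sigma": {},
        "spends": {},
        "model": {**cfg.model.__dict__, "widths": list(cfg.model.widths)},
        "train_template": dict(cfg.train_template.__dict__),
        "dataset_spec": {
            "n_patients": spec.n_patients,
            "image_shape": list(spec.image_shape),
            "labels": list(spec.labels),
            "seed": spec.seed,
        },
    }

    for eps in cfg.epsilon_grid:
        key = _epsilon_key(eps)
        model_cfg = replace(
            cfg.model,
            activation=(
                cfg.activation_dp if math.isfinite(eps) else cfg.activation_nonprivate
            ),
        )
        if math.isfinite(eps):
            base = replace(
                cfg.train_template, mode="dp", epsilon_target=eps, delta=delta,
                augment_rotate=False, augment_flip=False,
            )
            q = min(base.batch_size / len(prep_train), 1.0)
            steps = base.epochs * max(int(round(len(prep_train) / base.batch_size)), 1)
            sigma = calibrate_sigma(
                eps, delta, q, steps, tolerance=base.calibration_tolerance
            )
            base = replace(base, sigma=sigma)
            manifest["sigma"][key] = sigma
            logger.info("eps=%s: sigma=%.4f (q=%.4g, T=%d)", key, sigma, q, steps)
        else:
            epochs = cfg.nonprivate_epochs or cfg.train_template.epochs
            lr = cfg.nonprivate_learning_rate or cfg.train_template.learning_rate
            base = replace(
                cfg.train_template, mode="nonprivate", epsilon_target=None,
                sigma=None, epochs=epochs, learning_rate=lr,
            )
        for seed in cfg.seeds:
            cell_key = f"eps{key}_seed{seed}"
            try:
                t1 = time.time()
                model, table = train(
                    prep_train, model_cfg, replace(base, seed=seed), prep_test
                )
                table.to_csv(out / f"predictions_{cell_key}.csv")
                thresholds = {
                    l: youden_threshold(table.scores(l), table.truths(l))
                    for l in table.labels
                }
                metrics = metric_report(
                    table, thresholds, n_redraws=cfg.bootstrap_redraws, seed=seed
                )
                fair = fairness_report(
                    table, thresholds, reference_counts=reference_counts
                )
                spend = (
                    None if model.spend is None else {
                        "epsilon": model.spend.epsilon,
                        "delta": model.spend.delta,
                        "optimal_order": model.spend.optimal_order,
                    }
                )
                manifest["spends"][cell_key] = spend
                cells[cell_key] = {
                    "epsilon": key,
                    "seed": seed,
                    "metrics": metrics,
                    "fairness": fair,
                    "spend": spend,
                }
                logger.info(
                    "cell %s: macro AUROC %.4f (%.1fs)", cell_key,
                    metrics["macro"]["auroc"], time.time() - t1,
                )
            except Exception:
                logger.exception("cell %s failed; continuing", cell_key)

    bundle = {
        "cells": cells,
        "manifest": manifest,
        "aggregate": _aggregate(cells, cfg),
    }
    (out / "bundle.json").write_text(json.dumps(bundle, indent=2, default=float))
    return bundle


def _aggregate(cells: Mapping[str, dict], cfg: ExperimentConfig) -> dict:
    """Across-seed means/stds per ε, plus disparity trends along the grid."""
    agg: dict = {"per_epsilon": {}, "trends": {}}
    eps_keys = [_epsilon_key(e) for e in cfg.epsilon_grid]
    for key in eps_keys:
        rows = [c for c in cells.values() if c["epsilon"] == key]
        if not rows:
            continue
        auroc = [c["metrics"]["macro"]["auroc"] for c in rows]
        ptd_sex = [
            list(c["fairness"]["sex"]["parity_difference"].values())[0] for c in rows
        ]
        agg["per_epsilon"][key] = {
            "macro_auroc_mean": float(np.mean(auroc)),
            "macro_auroc_std": float(np.std(auroc)),
            "ptd_sex_mean": float(np.mean(ptd_sex)),
            "ptd_sex_std": float(np.std(ptd_sex)),
            "n_seeds": len(rows),
        }
    present = [e for e in cfg.epsilon_grid if _epsilon_key(e) in agg["per_epsilon"]]
    if len(present) >= 3:
        ptd = [agg["per_epsilon"][_epsilon_key(e)]["ptd_sex_mean"] for e in present]
        agg["trends"]["ptd_sex_vs_epsilon"] = disparity_trend(ptd, present)
    return agg


def desk_experiment(
    seed: int = 0,
    output_dir: str = "results/experiment",
    epsilon_grid: tuple[float, ...] | None = None,
    seeds: tuple[int, ...] = (0, 1, 2),
    n_patients: int = 465,
) -> ExperimentConfig:
    """The default desk-scale radiograph-like study.

    ~2000 records at 64x64 with four findings, resized to 32x32 in
    preprocessing; a compact group-normalized residual CNN; DP cells use
    Mish, lr 8e-3, 10 epochs at batch 128 with clipping norm 1.5, non-private
    cells ReLU, lr 5e-3, 8 epochs (all selected on the validation split).
    """
    spec = cxr_desk_spec(n_patients=n_patients, seed=seed)
    model = ModelConfig(
        ndim=2, widths=(8, 16, 32, 32), groups=32, activation="mish",
        n_outputs=len(spec.labels), stem_pool=True,
    )
    template = TrainConfig(
        mode="dp", learning_rate=8e-3, loss_weighting="inverted_class_frequency",
        clip_norm=1.5, batch_size=128, epochs=10, epsilon_target=1.0,
        delta=1e-3, seed=seed,
    )
    return ExperimentConfig(
        dataset_spec=spec,
        model=model,
        train_template=template,
        epsilon_grid=epsilon_grid or (0.5, 2.0, 8.0, math.inf),
        seeds=seeds,
        nonprivate_epochs=8,
        nonprivate_learning_rate=5e-3,
        train_extents=(32, 32),
        output_dir=output_dir,
    )


_CONFIG_KEYS = {
    "n_patients", "seed", "epsilon_grid", "seeds", "epochs",
    "nonprivate_epochs", "learning_rate", "nonprivate_learning_rate",
    "batch_size", "clip_norm", "delta", "bootstrap_redraws", "widths",
    "activation_dp", "activation_nonprivate", "split_fractions",
}


def load_experiment_config(path, output_dir: str = "results/experiment"):
    """Build an ExperimentConfig from a YAML file of scalar overrides.

    Unknown keys raise a validation error naming the key; absent keys fall
    back to the desk defaults.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; known keys: "
            f"{sorted(_CONFIG_KEYS)}"
        )
    grid = raw.get("epsilon_grid")
    if grid is not None:
        grid = tuple(math.inf if g in ("inf", 0) else float(g) for g in grid)
    cfg = desk_experiment(
        seed=int(raw.get("seed", 0)),
        output_dir=output_dir,
        epsilon_grid=grid,
        seeds=tuple(raw.get("seeds", (0, 1, 2))),
        n_patients=int(raw.get("n_patients", 465)),
    )
    template = cfg.train_template
    for key in ("epochs", "learning_rate", "batch_size", "clip_norm"):
        if key in raw:
            template = replace(template, **{key: raw[key]})
    model = cfg.model
    if "widths" in raw:
        model = replace(model, widths=tuple(raw["widths"]))
    updates: dict = {"train_template": template, "model": model}
    for key in (
        "nonprivate_epochs", "nonprivate_learning_rate", "delta",
        "bootstrap_redraws", "activation_dp", "activation_nonprivate",
    ):
        if key in raw:
            updates[key] = raw[key]
    if "split_fractions" in raw:
        updates["split_fractions"] = tuple(raw["split_fractions"])
    return replace(cfg, **updates)


def report(bundle: Mapping, output_dir: str | Path = "results/report") -> dict:
    """Emit tables and figures for a completed bundle.

    Writes a CSV whose rows are subgroups (Total, sex groups, age bins) and
    whose columns carry AUROC μ/σ and PtD μ/σ at each ε, plus a line plot of
    macro AUROC versus ε with the non-private value as a dashed reference.
    Returns {"table": path, "figure": path}.
    """
    cells = bundle["cells"]
    if not cells:
        raise ValueError("empty bundle: no completed cells to report")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    eps_keys = list(dict.fromkeys(c["epsilon"] for c in cells.values()))

    def seed_rows(key):
        return [c for c in cells.values() if c["epsilon"] == key]

    subgroup_names = ["Total"]
    sample = next(iter(cells.values()))
    sex_groups = sorted(sample["fairness"]["sex"]["parity_difference"])
    age_groups = sorted(sample["fairness"]["age_group"]["parity_difference"])
    subgroup_names += [f"sex={g}" for g in sex_groups]
    subgroup_names += [f"age={g}" for g in age_groups]

    records = []
    for name in subgroup_names:
        row: dict = {"subgroup": name}
        for key in eps_keys:
            rows = seed_rows(key)
            aurocs = [c["metrics"]["macro"]["auroc"] for c in rows]
            row[f"auroc_mu_eps{key}"] = float(np.mean(aurocs))
            row[f"auroc_sigma_eps{key}"] = float(np.std(aurocs))
            if name == "Total":
                ptds = [0.0] * len(rows)
            elif name.startswith("sex="):
                g = name.split("=", 1)[1]
                ptds = [
                    c["fairness"]["sex"]["parity_difference"].get(g, float("nan"))
                    for c in rows
                ]
            else:
                g = name.split("=", 1)[1]
                ptds = [
                    c["fairness"]["age_group"]["parity_difference"].get(
                        g, float("nan")
                    )
                    for c in rows
                ]
            row[f"ptd_mu_eps{key}"] = float(np.nanmean(ptds))
            row[f"ptd_sigma_eps{key}"] = float(np.nanstd(ptds))
        records.append(row)
    frame = pd.DataFrame(records)
    table_path = out / "summary_table.csv"
    frame.to_csv(table_path, index=False)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    finite_keys = [k for k in eps_keys if k != "inf"]
    xs = [float(k) for k in finite_keys]
    ys = [
        float(np.mean([c["metrics"]["macro"]["auroc"] for c in seed_rows(k)]))
        for k in finite_keys
    ]
    errs = [
        float(np.std([c["metrics"]["macro"]["auroc"] for c in seed_rows(k)]))
        for k in finite_keys
    ]
    ax.errorbar(xs, ys, yerr=errs, marker="o", label="DP training")
    if "inf" in eps_keys:
        ref = float(
            np.mean([c["metrics"]["macro"]["auroc"] for c in seed_rows("inf")])
        )
        ax.axhline(ref, linestyle="--", color="gray", label="non-private")
    ax.set_xscale("log")
    ax.set_xlabel("privacy budget ε")
    ax.set_ylabel("macro AUROC")
    ax.legend()
    fig.tight_layout()
    figure_path = out / "auroc_vs_epsilon.png"
    fig.savefig(figure_path, dpi=150)
    plt.close(fig)
    return {"table": str(table_path), "figure": str(figure_path)}
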