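"""Experiment sweeps: models x grids x splits x batch sizes, repeated runs.

Mirrors the published evaluation protocol: every configuration is trained
``n_runs`` times with run-specific seeds fanned out from one master seed,
metrics are computed on the requested fold, and mean-aggregated rows are
appended alongside the per-run rows.  Prediction-scatter and per-class-MAE
data are emitted as plain tables (CSV-ready), not rendered figures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import SplitAssignment, split_by_concentration, split_by_cultivar
from .evaluate import per_class_mae, regression_metrics
from .models import train_model
from .nn import ResNet1DConfig

RUN_COLUMNS = [
    "model",
    "grid",
    "strategy",
    "batch_size",
    "run",
    "seed",
    "fold",
    "r2",
    "rmse",
    "mae",
    "n_records",
]


@dataclass
class SweepConfig:
    models: tuple[str, ...] = ("resnet", "svm", "xgb")
    grids: tuple[int, ...] = (1, 2, 3, 4, 5)
    strategies: tuple[str, ...] = ("cultivar", "concentration")
    batch_sizes: tuple[int, ...] = (32, 64, 128, 256)
    n_runs: int = 5
    eval_fold: str = "val"
    master_seed: int = 0
    val_cultivar: str | None = None
    test_cultivar: str | None = None
    held_out_map: dict | None = None
    resnet_config: ResNet1DConfig = field(default_factory=ResNet1DConfig)

    def __post_init__(self) -> None:
        if not set(self.grids) <= set(range(1, 6)):
            raise ValueError("grids must be within 1..5")
        if not set(self.models) <= {"resnet", "svm", "xgb"}:
            raise ValueError("models must be among resnet/svm/xgb")
        if not set(self.strategies) <= {"cultivar", "concentration"}:
            raise ValueError("strategies must be cultivar/concentration")


def make_split(
    table: pd.DataFrame, strategy: str, config: SweepConfig
) -> SplitAssignment:
    if strategy == "cultivar":
        return split_by_cultivar(
            table,
            val_cultivar=config.val_cultivar,
            test_cultivar=config.test_cultivar,
            seed=config.master_seed,
        )
    return split_by_concentration(
        table, held_out_map=config.held_out_map, seed=config.master_seed
    )


def _run_seeds(master_seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(master_seed).generate_state(n) % 2**31]


def run_sweep(
    tables: dict[int, pd.DataFrame], config: SweepConfig
) -> tuple[pd.DataFrame, dict]:
    """Run every configured (model, grid, strategy[, batch], run) cell.

    Returns the results table (per-run rows plus ``run = "mean"`` aggregate
    rows) and a dict of plot data: prediction scatter and per-class MAE for
    each aggregate cell, computed from the last run's predictions.
    """
    missing = set(config.grids) - set(tables)
    if missing:
        raise ValueError(f"no feature table for grid size(s) {sorted(missing)}")
    rows: list[dict] = []
    plot_data: dict[str, pd.DataFrame] = {}
    seeds = _run_seeds(config.master_seed, config.n_runs)

    for strategy in config.strategies:
        for g in config.grids:
            table = tables[g]
            folds = make_split(table, strategy, config)
            eval_sel = folds.folds == config.eval_fold
            y_true = table.loc[eval_sel, "sugar_pct"].to_numpy(float)
            for model_kind in config.models:
                batch_sizes = config.batch_sizes if model_kind == "resnet" else (None,)
                for batch in batch_sizes:
                    run_metrics = []
                    y_pred = None
                    for run, seed in enumerate(seeds):
                        kwargs = {}
                        if model_kind == "resnet":
                            kwargs["config"] = ResNet1DConfig(
                                **{
                                    **config.resnet_config.__dict__,
                                    "batch_size": batch,
                                }
                            )
                        fitted = train_model(
                            model_kind, table, folds, seed=seed, **kwargs
                        )
                        y_pred = fitted.predict(table.loc[eval_sel])
                        r2, rmse, mae = regression_metrics(y_true, y_pred)
                        run_metrics.append((r2, rmse, mae))
                        rows.append(
                            dict(
                                model=model_kind,
                                grid=g,
                                strategy=strategy,
                                batch_size=batch if batch is not None else 0,
                                run=run,
                                seed=seed,
                                fold=config.eval_fold,
                                r2=r2,
                                rmse=rmse,
                                mae=mae,
                                n_records=len(y_true),
                            )
                        )
                    mean = np.mean(run_metrics, axis=0)
                    rows.append(
                        dict(
                            model=model_kind,
                            grid=g,
                            strategy=strategy,
                            batch_size=batch if batch is not None else 0,
                            run="mean",
                            seed=config.master_seed,
                            fold=config.eval_fold,
                            r2=mean[0],
                            rmse=mean[1],
                            mae=mean[2],
                            n_records=len(y_true),
                        )
                    )
                    key = f"{strategy}/{model_kind}/g{g}" + (
                        f"/b{batch}" if batch else ""
                    )
                    plot_data[f"scatter/{key}"] = pd.DataFrame(
                        {"y_true": y_true, "y_pred": y_pred}
                    )
                    pcm = per_class_mae(y_true, y_pred)
                    plot_data[f"per_class_mae/{key}"] = pd.DataFrame(
                        {"sugar_pct": list(pcm), "mae": list(pcm.values())}
                    )
    return pd.DataFrame(rows, columns=RUN_COLUMNS), plot_data


def rgb_vs_hsi(
    hsi_tables: dict[int, pd.DataFrame],
    rgb_tables: dict[int, pd.DataFrame],
    config: SweepConfig,
) -> pd.DataFrame:
    """Identical sweep on paired RGB and hyperspectral feature tables.

    Returns one row per (model, grid, feature set) aggregate with suffixed
    metric columns for direct comparison.  The RGB tables must describe the
    same scenes (same image indices) as the hyperspectral ones.
    """
    for g in config.grids:
        if not hsi_tables[g]["image_index"].equals(rgb_tables[g]["image_index"]):
            raise ValueError(f"grid {g}: RGB and HSI tables cover different scenes")
    results = []
    for name, tables in (("hsi", hsi_tables), ("rgb", rgb_tables)):
        res, _ = run_sweep(tables, config)
        agg = res[res["run"] == "mean"].copy()
        agg["features"] = name
        results.append(agg)
    both = pd.concat(results, ignore_index=True)
    paired = both.pivot_table(
        index=["model", "grid", "strategy", "batch_size"],
        columns="features",
        values=["r2", "rmse", "mae"],
        dropna=False,
    )
    paired.columns = [f"{m}_{f}" for m, f in paired.columns]
    return paired.reset_index()
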