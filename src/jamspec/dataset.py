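"""Tabular per-subregion datasets and leakage-aware train/val/test splits.

Each grid configuration yields one table: one row per surviving grid cell,
with the unit-norm spectral feature in columns ``band_0001..band_NNNN``
followed by the metadata (sugar %, cultivar, image index, grid position,
thickness, view, distance, pixel count).

Two splitting strategies are implemented, both operating on groups rather
than rows so that no image ever straddles folds:

* **cultivar split** — 6 of 8 cultivars train, 1 validation, 1 test; the
  evaluation cultivars are completely unseen during training.
* **concentration split** — per cultivar, a few sugar concentrations are
  held out for test/validation; every cultivar is seen in training but the
  held-out concentrations are not.  The default hold-out map reserves
  14 test and 12 validation of the 88 (cultivar, concentration) cells
  (~15.9% / ~13.6%; ~70.5% train).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .design import AcquisitionDesign, CaptureMeta
from .segment import GridCellFeature

METADATA_COLUMNS = [
    "sugar_pct",
    "cultivar",
    "image_index",
    "grid_size",
    "cell_row",
    "cell_col",
    "thickness_cm",
    "view",
    "distance_cm",
    "n_pixels",
]


class IntegrityError(ValueError):
    """Duplicate or inconsistent records in a table."""


class SplitError(ValueError):
    """Invalid split request or a split violating its guarantees."""


def band_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("band_")]


def build_table(
    features_per_image: list[tuple[CaptureMeta, list[GridCellFeature]]],
) -> pd.DataFrame:
    """Assemble one grid configuration's table from per-image features."""
    rows = []
    seen: set[tuple[int, int, int]] = set()
    n_bands = None
    for meta, feats in features_per_image:
        for f in feats:
            key = (meta.image_index, f.cell[0], f.cell[1])
            if key in seen:
                raise IntegrityError(
                    f"duplicate record for image {meta.image_index} cell {f.cell}"
                )
            seen.add(key)
            if n_bands is None:
                n_bands = f.feature.shape[0]
            elif f.feature.shape[0] != n_bands:
                raise IntegrityError("inconsistent feature lengths across records")
            row = {
                f"band_{i + 1:04d}": v for i, v in enumerate(f.feature)
            }
            row.update(
                sugar_pct=meta.sugar_pct,
                cultivar=meta.cultivar,
                image_index=meta.image_index,
                grid_size=f.grid_size,
                cell_row=f.cell[0],
                cell_col=f.cell[1],
                thickness_cm=meta.thickness_cm,
                view=meta.view,
                distance_cm=meta.distance_cm,
                n_pixels=f.n_pixels,
            )
            rows.append(row)
    if not rows:
        raise IntegrityError("no records to tabulate")
    bands = [f"band_{i + 1:04d}" for i in range(n_bands)]
    return pd.DataFrame(rows, columns=bands + METADATA_COLUMNS)


def write_csv(table: pd.DataFrame, path) -> None:
    """RFC 4180 CSV with full float precision (round-trips to >=12 digits)."""
    table.to_csv(path, index=False, float_format="%.17g")


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Splits


@dataclass
class SplitAssignment:
    """Fold label per record plus the manifest of held-out units."""

    strategy: str
    folds: pd.Series
    seed: int | None
    manifest: dict = field(default_factory=dict)

    def indices(self, fold: str) -> np.ndarray:
        return np.flatnonzero((self.folds == fold).to_numpy())

    def counts(self) -> dict[str, int]:
        return self.folds.value_counts().to_dict()


def _assert_no_image_leakage(table: pd.DataFrame, folds: pd.Series) -> None:
    per_image = table.groupby("image_index", sort=False).apply(
        lambda df: folds.loc[df.index].nunique(), include_groups=False
    )
    if (per_image > 1).any():
        bad = per_image[per_image > 1].index.tolist()[:5]
        raise SplitError(f"images straddle folds (leakage): {bad}")


def split_by_cultivar(
    table: pd.DataFrame,
    val_cultivar: str | None = None,
    test_cultivar: str | None = None,
    seed: int | None = None,
) -> SplitAssignment:
    """Hold out one whole cultivar for validation and one for test.

    When a held-out cultivar is not specified it is chosen by the seeded
    generator; the remaining six (of eight, in the default design) train.
    """
    cultivars = sorted(table["cultivar"].unique())
    rng = np.random.default_rng(seed)
    if test_cultivar is None:
        test_cultivar = str(rng.choice(cultivars))
    if val_cultivar is None:
        remaining = [c for c in cultivars if c != test_cultivar]
        val_cultivar = str(rng.choice(remaining))
    for name in (val_cultivar, test_cultivar):
        if name not in cultivars:
            raise SplitError(f"unknown cultivar {name!r}")
    if val_cultivar == test_cultivar:
        raise SplitError("validation and test cultivar must differ")

    folds = pd.Series(
        np.where(
            table["cultivar"] == test_cultivar,
            "test",
            np.where(table["cultivar"] == val_cultivar, "val", "train"),
        ),
        index=table.index,
    )
    _assert_no_image_leakage(table, folds)
    train_cultivars = [c for c in cultivars if c not in (val_cultivar, test_cultivar)]
    assignment = SplitAssignment(
        strategy="cultivar",
        folds=folds,
        seed=seed,
        manifest={
            "train_cultivars": train_cultivars,
            "val_cultivar": val_cultivar,
            "test_cultivar": test_cultivar,
            "train_cultivar_fraction": len(train_cultivars) / len(cultivars),
        },
    )
    return assignment


def rotating_holdout_map(
    cultivars: list[str],
    levels: list[float],
    n_test_cells: int | None = None,
    n_val_cells: int | None = None,
) -> dict[str, dict[str, list[float]]]:
    """Deterministic per-cultivar concentration hold-out pattern.

    Cultivar i holds out test concentrations at level indices
    ``{2i mod L}`` (plus ``{(2i + L//2) mod L}`` for the leading cultivars
    until ``n_test_cells`` is reached) and validation concentrations at the
    indices shifted by one.  For the default 8 cultivars x 11 levels with
    14 test / 12 val cells this reproduces the published marginal fractions
    70.5% / 15.9% / 13.6%.
    """
    n_c, n_l = len(cultivars), len(levels)
    if n_l < 3:
        raise SplitError(
            "need at least 3 concentration levels to hold out test and val "
            "cells while keeping one for training"
        )
    if n_test_cells is None:
        n_test_cells = 14 if (n_c, n_l) == (8, 11) else n_c
    if n_val_cells is None:
        n_val_cells = 12 if (n_c, n_l) == (8, 11) else n_c
    for n, what in ((n_test_cells, "test"), (n_val_cells, "val")):
        if not n_c <= n <= 2 * n_c:
            raise SplitError(
                f"{what} cell count {n} not in [{n_c}, {2 * n_c}] "
                "(1-2 cells per cultivar)"
            )
    if (n_test_cells > n_c or n_val_cells > n_c) and n_l < 5:
        raise SplitError("two held-out cells per cultivar need >= 5 levels")
    half = n_l // 2
    out: dict[str, dict[str, list[float]]] = {}
    for i, cultivar in enumerate(sorted(cultivars)):
        base = (2 * i) % n_l
        test_idx = [base]
        if i < n_test_cells - n_c:
            test_idx.append((base + half) % n_l)
        val_idx = [(base + 1) % n_l]
        if i < n_val_cells - n_c:
            val_idx.append((base + half + 1) % n_l)
        if set(test_idx) & set(val_idx):
            raise SplitError("rotating pattern collided; too few levels")
        srt = sorted(levels)
        out[cultivar] = {
            "test": [float(srt[k]) for k in test_idx],
            "val": [float(srt[k]) for k in val_idx],
        }
    return out


def default_holdout_map() -> dict[str, dict[str, list[float]]]:
    """The packaged default hold-out map (8 cultivars x 11 levels)."""
    ref = importlib.resources.files("jamspec.data") / "holdout_default.yaml"
    return yaml.safe_load(ref.read_text())


def split_by_concentration(
    table: pd.DataFrame,
    held_out_map: dict[str, dict[str, list[float]]] | None = None,
    seed: int | None = None,
) -> SplitAssignment:
    """Hold out (cultivar, concentration) cells; every cultivar trains.

    ``held_out_map`` maps cultivar -> {"test": [...], "val": [...]} in sugar
    % w/w.  An empty map sends everything to train.  The default is the
    packaged rotating pattern when the table has the full 8x11 design, else
    a freshly generated rotating pattern over the table's own cultivars and
    levels.
    """
    cultivars = sorted(table["cultivar"].unique())
    levels = sorted(table["sugar_pct"].unique())
    if held_out_map is None:
        if (len(cultivars), len(levels)) == (8, 11):
            held_out_map = default_holdout_map()
        else:
            held_out_map = rotating_holdout_map(cultivars, levels)

    cell_fold: dict[tuple[str, float], str] = {}
    for cultivar, spec_map in held_out_map.items():
        if cultivar not in cultivars:
            raise SplitError(f"hold-out map names unknown cultivar {cultivar!r}")
        test_levels = {float(v) for v in spec_map.get("test", [])}
        val_levels = {float(v) for v in spec_map.get("val", [])}
        if test_levels & val_levels:
            raise SplitError(
                f"cultivar {cultivar!r}: test and val concentrations overlap"
            )
        for lv in test_levels:
            cell_fold[(cultivar, lv)] = "test"
        for lv in val_levels:
            cell_fold[(cultivar, lv)] = "val"

    n_cells = len(cultivars) * len(levels)
    fold_cells = {"train": 0, "val": 0, "test": 0}
    for c in cultivars:
        train_levels = [
            lv for lv in levels if cell_fold.get((c, float(lv)), "train") == "train"
        ]
        if not train_levels:
            raise SplitError(f"cultivar {c!r} has no training concentrations")
        for lv in levels:
            fold_cells[cell_fold.get((c, float(lv)), "train")] += 1

    keys = list(zip(table["cultivar"], table["sugar_pct"].astype(float)))
    folds = pd.Series([cell_fold.get(k, "train") for k in keys], index=table.index)
    _assert_no_image_leakage(table, folds)
    manifest = {
        "held_out_map": held_out_map,
        "cell_counts": fold_cells,
        "cell_fractions_pct": {
            k: round(100.0 * v / n_cells, 1) for k, v in fold_cells.items()
        },
    }
    return SplitAssignment(
        strategy="concentration", folds=folds, seed=seed, manifest=manifest
    )
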