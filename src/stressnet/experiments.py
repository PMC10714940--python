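"""Experiment harness: spectral-subset, temporal-window and ablation grids.

Each grid cell trains a model from scratch (He initialization) on the
requested view of a sequence archive and reports the final training loss,
best validation accuracy (percent), and macro precision/recall — the
schema of the study's result tables.  The train/validation split is shared
across all cells of a grid so cells differ only in the factor under test;
every row records its complete configuration and seeds, so any single cell
can be re-run and reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import StressNet, resolve_variant
from .roi_sequences import (InvalidSubsetError, InvalidWindowError, logger,
                            subset_archive, window_archive)
from .train_eval import TrainConfig, evaluate, split_dataset, train


@dataclass
class ExperimentGrid:
    """Axes of the experiment matrix; every cell is independently seeded."""
    spectral_subsets: tuple = ("RGB", "RGB-NIR", "RGB-Re", "All")
    temporal_windows: tuple = (3, 6, 9, 11, 13)
    variants: tuple = ("full",)
    backbones: tuple = ("compact",)
    seeds: tuple = (0,)
    split_seed: int = 0

    def __post_init__(self):
        for name in ("spectral_subsets", "temporal_windows", "variants",
                     "backbones", "seeds"):
            vals = tuple(getattr(self, name))
            if not vals:
                raise ValueError(f"grid axis {name} is empty")
            # duplicate cells are collapsed: each runs once
            setattr(self, name, tuple(dict.fromkeys(vals)))


RESULT_COLUMNS = ["experiment", "backbone", "variant", "subset", "n_days",
                  "seed", "split_seed", "train_loss", "val_accuracy_pct",
                  "precision", "recall"]


def _run_cell(archive, backbone, variant, config: TrainConfig, seed, split_seed,
              subset=None, n_days=None, model_kwargs=None) -> dict:
    data = archive
    if subset is not None:
        data = subset_archive(data, subset)
    if n_days is not None:
        data = window_archive(data, n_days)
    tr, va = split_dataset(data, config.train_fraction, split_seed)
    kwargs = dict(model_kwargs or {})
    kwargs.update(backbone=backbone, variant=variant,
                  input_channels=len(data["channel_names"]), seed=seed)
    model = StressNet(**kwargs)
    cfg = TrainConfig(**{**config.__dict__, "seed": seed})
    model, hist = train(model, tr, va, cfg)
    report = evaluate(model, va, stats=hist["norm_stats"])
    return {
        "backbone": backbone,
        "variant": resolve_variant(variant),
        "subset": subset,
        "n_days": n_days,
        "seed": seed,
        "split_seed": split_seed,
        "train_loss": hist["train_loss"][-1] if hist["train_loss"] else np.nan,
        "val_accuracy_pct": 100.0 * (hist["best_val_accuracy"] or 0.0),
        "precision": report.macro_precision,
        "recall": report.macro_recall,
    }


def run_spectral_analysis(archive: dict, grid: ExperimentGrid,
                          config: TrainConfig,
                          model_kwargs: dict | None = None) -> pd.DataFrame:
    """Train/evaluate per (backbone, spectral subset) using all dates.

    The first conv layer is rebuilt for each subset's channel count.
    Subsets whose channels are absent from the archive are skipped with a
    logged warning.
    """
    rows = []
    for backbone in grid.backbones:
        for subset in grid.spectral_subsets:
            for seed in grid.seeds:
                try:
                    row = _run_cell(archive, backbone, grid.variants[0],
                                    config, seed, grid.split_seed,
                                    subset=subset, model_kwargs=model_kwargs)
                except InvalidSubsetError as e:
                    logger.warning("skipping subset %s: %s", subset, e)
                    continue
                row["experiment"] = "spectral"
                rows.append(row)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_temporal_analysis(archive: dict, grid: ExperimentGrid,
                          config: TrainConfig,
                          model_kwargs: dict | None = None) -> pd.DataFrame:
    """Train/evaluate per (backbone, N days) using all channels.

    Sequences are truncated to their first N frames.  Windows exceeding the
    archive length are skipped with a logged warning.
    """
    rows = []
    for backbone in grid.backbones:
        for n_days in grid.temporal_windows:
            for seed in grid.seeds:
                try:
                    row = _run_cell(archive, backbone, grid.variants[0],
                                    config, seed, grid.split_seed,
                                    n_days=int(n_days), model_kwargs=model_kwargs)
                except InvalidWindowError as e:
                    logger.warning("skipping window %s: %s", n_days, e)
                    continue
                row["experiment"] = "temporal"
                rows.append(row)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_ablation(archive: dict, grid: ExperimentGrid, config: TrainConfig,
                 axis: str = "none",
                 model_kwargs: dict | None = None) -> pd.DataFrame:
    """Train/evaluate the architecture variants (Cases I–III and full).

    ``axis`` extends the comparison over spectral subsets or temporal
    windows; with ``axis='none'`` each (variant, backbone) runs once on the
    full archive.  All cells share the grid's data split.
    """
    if axis == "spectral":
        cells = [dict(subset=s) for s in grid.spectral_subsets]
    elif axis == "temporal":
        cells = [dict(n_days=int(n)) for n in grid.temporal_windows]
    elif axis == "none":
        cells = [dict()]
    else:
        raise ValueError(f"unknown ablation axis {axis!r}")
    rows = []
    for variant in grid.variants:
        for backbone in grid.backbones:
            for cell in cells:
                for seed in grid.seeds:
                    try:
                        row = _run_cell(archive, backbone, variant, config,
                                        seed, grid.split_seed,
                                        model_kwargs=model_kwargs, **cell)
                    except (InvalidSubsetError, InvalidWindowError) as e:
                        logger.warning("skipping cell %s: %s", cell, e)
                        continue
                    row["experiment"] = f"ablation-{axis}"
                    rows.append(row)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def aggregate_over_seeds(results: pd.DataFrame) -> pd.DataFrame:
    """Mean metrics over replicate seeds per grid cell."""
    keys = ["experiment", "backbone", "variant", "subset", "n_days"]
    return (results.groupby(keys, dropna=False)
            [["train_loss", "val_accuracy_pct", "precision", "recall"]]
            .mean().reset_index())


def save_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, index=False)


def load_results(path) -> pd.DataFrame:
    return pd.read_csv(path)
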