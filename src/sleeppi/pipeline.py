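"""End-to-end orchestration: simulate -> score -> clean -> extract ->
cluster -> validate, with seeded reproducibility and a run record that
contains every number needed to regenerate the stage tables without
re-running training.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import (
    build_selection_grid,
    elbow_select,
    fit_kmeans,
    assign,
    select_architecture,
    wcss_curve,
)
from .errors import SleepPIError
from .features import TrainingConfig, encode, fit_final_autoencoder, fit_pca, crossval_grid
from .preprocessing import (
    OutlierBounds,
    build_feature_matrix,
    clean,
    filter_sleep_disturbed,
    split,
)
from .scoring import score_table
from .synthetic import SyntheticConfig, generate_survey
from .validation import build_report

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every knob of the analysis in one place; seeds are always explicit."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    input_table: str | None = None  # CSV path; None -> simulate
    gsrs_convention: str = "sum0"
    include_scored_instrument_items: bool = True
    bounds: OutlierBounds = field(default_factory=OutlierBounds)
    split_fraction: float = 0.8
    J_grid: tuple = tuple(range(1, 11))
    cv_folds: int = 10
    epochs: int = 100
    batch_size: int = 64
    k_values: tuple = tuple(range(1, 11))
    k_focus: tuple = (2, 3, 4)
    restarts: int = 10
    run_cv_grid: bool = True
    seed: int = 0
    output_dir: str | None = None


def _plan(config: PipelineConfig) -> dict:
    return {
        "stages": [
            "simulate" if config.input_table is None else f"load:{config.input_table}",
            "score", "clean", "psqi-filter", "split",
            f"pca+autoencoder grid J={list(config.J_grid)}",
            f"kmeans k={list(config.k_values)} focus={list(config.k_focus)}",
            "elbow", "validate(train,test)",
        ],
        "seed": config.seed,
        "output_dir": config.output_dir,
    }


def run_pipeline(config: PipelineConfig, dry_run: bool = False) -> dict:
    """Execute every stage in order and return the run record.

    The record holds the cleaning-stage counts, the CV grid over J, the
    (feature set, k) selection grid, the WCSS elbow curve, the chosen
    architecture and cluster count, per-partition cluster labels and
    validation reports, and a manifest of seeds and versions.  When
    ``config.output_dir`` is set each table is also persisted as delimited
    text.
    """
    if dry_run:
        return {"plan": _plan(config)}
    record: dict = {"config_seed": config.seed, "versions": {
        "sleeppi": __version__, "python": platform.python_version(),
    }}
    stage = "simulate"
    try:
        # ------------------------------------------------------------ data
        if config.input_table is None:
            table, manifest = generate_survey(config.synthetic)
            record["artifact_manifest_counts"] = (
                manifest["artifact"].value_counts().to_dict()
            )
        else:
            table = pd.read_csv(config.input_table)
            manifest = None

        stage = "clean"
        cleaned, counts = clean(table, config.bounds)

        stage = "score"
        scored = score_table(cleaned, gsrs_convention=config.gsrs_convention)

        stage = "psqi-filter"
        disturbed = filter_sleep_disturbed(scored)
        counts["not_sleep_disturbed_removed"] = len(scored) - len(disturbed)
        counts["analysis_rows"] = len(disturbed)
        record["stage_counts"] = counts

        stage = "split"
        sp = split(disturbed, config.split_fraction, seed=config.seed)
        record["split"] = {"train": len(sp.train_ids), "test": len(sp.test_ids)}

        stage = "features"
        fm_train, fm_test = build_feature_matrix(
            disturbed, sp,
            include_scored_instrument_items=config.include_scored_instrument_items,
        )
        record["d"] = fm_train.d

        pca_model, Z_pca_train = fit_pca(fm_train.X)
        record["pca_components"] = pca_model.n_components
        record["pca_explained_variance"] = pca_model.explained_variance.tolist()

        if config.run_cv_grid:
            grid_table, _ = crossval_grid(
                fm_train.X, J_grid=config.J_grid, folds=config.cv_folds,
                epochs=config.epochs, batch_size=config.batch_size, seed=config.seed,
            )
            record["cv_grid"] = grid_table.to_dict("records")
        else:
            grid_table = None

        feature_sets = {"raw": fm_train.X, "pca": Z_pca_train}
        dae_models = {}
        for J in config.J_grid:
            cfg = TrainingConfig(
                epochs=config.epochs, batch_size=config.batch_size,
                seed=(config.seed + 17 * int(J)) % (2**31),
            )
            dae_models[int(J)] = fit_final_autoencoder(fm_train.X, int(J), cfg)
            feature_sets[f"dae_J={int(J)}"] = encode(dae_models[int(J)], fm_train.X)

        stage = "cluster-selection"
        k_internal = [k for k in config.k_values if k >= 2]
        sel_grid = build_selection_grid(
            feature_sets, k_values=k_internal, restarts=config.restarts, seed=config.seed
        )
        winner, ranking = select_architecture(sel_grid, k_focus=config.k_focus)
        record["selection_grid"] = sel_grid.to_dict("records")
        record["feature_ranking"] = ranking.to_dict("records")
        record["selected_feature_set"] = winner
        Z_train = feature_sets[winner]

        stage = "elbow"
        curve = wcss_curve(Z_train, k_values=config.k_values,
                           restarts=config.restarts, seed=config.seed)
        elbow = elbow_select(curve)
        record["wcss_curve"] = {int(k): float(v) for k, v in curve.items()}
        record["selected_k"] = elbow.k
        record["no_elbow"] = elbow.no_elbow

        stage = "final-clustering"
        solution = fit_kmeans(Z_train, elbow.k, restarts=config.restarts, seed=config.seed)
        train_labels = solution.labels
        if winner.startswith("dae"):
            J_sel = int(winner.split("=")[1])
            Z_test = encode(dae_models[J_sel], fm_test.X)
            record["selected_J"] = J_sel
        elif winner == "pca":
            Z_test = pca_model.transform(fm_test.X)
        else:
            Z_test = fm_test.X
        test_labels = assign(solution, Z_test) if len(Z_test) else np.array([], dtype=int)
        record["cluster_sizes_train"] = np.bincount(train_labels, minlength=elbow.k).tolist()
        record["cluster_sizes_test"] = (
            np.bincount(test_labels, minlength=elbow.k).tolist() if len(Z_test) else []
        )
        record["internal_metrics"] = {
            "wcss": solution.wcss, "ch_index": solution.ch_index,
            "silhouette": solution.silhouette,
        }

        stage = "validate"
        indexed = disturbed.set_index("respondent_id", drop=False)
        train_rows = indexed.loc[list(sp.train_ids)]
        test_rows = indexed.loc[list(sp.test_ids)]
        report_train = build_report(train_rows, train_labels, "train")
        record["report_train"] = report_train.rows.to_dict("records")
        if len(test_rows) and len(np.unique(test_labels)) >= 2:
            report_test = build_report(test_rows, test_labels, "test")
            record["report_test"] = report_test.rows.to_dict("records")
        else:
            report_test = None

        # 3-D coordinate export: the externally discriminative score axes
        def coords(rows, labels):
            out = rows[["respondent_id", "psqi_global", "gsrs_total", "nq_moderation"]].copy()
            out["berlin_high"] = (rows["berlin_risk"] == "high").astype(int)
            out["cluster"] = labels
            if "true_cluster" in rows.columns:
                out["true_cluster"] = rows["true_cluster"].to_numpy()
            return out.reset_index(drop=True)

        coords_train = coords(train_rows, train_labels)
        coords_test = coords(test_rows, test_labels) if len(test_rows) else None
        record["plan"] = _plan(config)
    except Exception as exc:  # annotate the failing stage before re-raising
        raise SleepPIError(f"pipeline stage '{stage}' failed: {exc}") from exc

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "run_record.json", "w") as fh:
            json.dump(_jsonable(record), fh, indent=2)
        pd.DataFrame([counts]).to_csv(out / "stage_counts.csv", index=False)
        if grid_table is not None:
            grid_table.to_csv(out / "cv_grid.csv", index=False)
        sel_grid.to_csv(out / "selection_grid.csv", index=False)
        pd.DataFrame(
            {"k": list(curve), "wcss": [curve[k] for k in curve]}
        ).to_csv(out / "wcss_curve.csv", index=False)
        coords_train.to_csv(out / "coordinates_train.csv", index=False)
        if coords_test is not None:
            coords_test.to_csv(out / "coordinates_test.csv", index=False)
        report_train.rows.to_csv(out / "report_train.csv", index=False)
        if report_test is not None:
            report_test.rows.to_csv(out / "report_test.csv", index=False)

    record["coordinates_train"] = coords_train
    if coords_test is not None:
        record["coordinates_test"] = coords_test
    return record


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items() if not isinstance(v, pd.DataFrame)}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
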