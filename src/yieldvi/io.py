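"""Plot-table I/O and the end-to-end pipeline run.

The pipeline mirrors the full study workflow on any plot-level band
table: compute the 35 vegetation indices, rank them by Pearson
correlation and random-forest importance, threshold, combine, run
patience-limited RFE per base model, and cross-validate every model ×
subset combination (all features, PC, RF, union, intersection, and the
model's own PCRF-RFE subset).  Reports are JSON-first (CSV summaries
are derived views), carry the package version, a config hash and all
seeds, and contain no timestamps, so identical configurations produce
byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
import pandas as pd

from . import __version__
from .evaluate import kfold_cv
from .feature_sets import FeatureSubset
from .models import ModelSpec
from .selection import (
    ForestConfig,
    RFEConfig,
    apply_threshold,
    combine_subsets,
    pearson_ranking,
    rf_ranking,
    rfe_select,
)
from .vegindex import BAND_NAMES, compute_all, list_indices

__all__ = ["RunConfig", "SchemaError", "read_plot_table", "write_plot_table", "run_pipeline"]

logger = logging.getLogger("yieldvi")

PLOT_COLUMNS = (
    "plot_id",
    "treatment",
    "cultivar",
    "rep",
    *BAND_NAMES,
    "yield_t_ha",
)


class SchemaError(ValueError):
    """The plot table does not conform to the documented CSV schema."""


def read_plot_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a plot-level CSV table.

    Expects the header ``plot_id,treatment,cultivar,rep,blue,green,red,
    red_edge,nir,yield_t_ha``.  Malformed rows (non-numeric band,
    non-positive yield) are rejected with their 1-based file line
    numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in PLOT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    bad_lines = []
    for col in (*BAND_NAMES, "yield_t_ha"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if col == "yield_t_ha":
            bad |= vals <= 0
        for i in df.index[bad]:
            bad_lines.append((int(i) + 2, col))  # +2: header + 1-based
        df[col] = vals
    if bad_lines:
        detail = ", ".join(f"line {ln} ({col})" for ln, col in sorted(bad_lines))
        raise SchemaError(f"{path}: malformed row(s): {detail}")
    return df[list(PLOT_COLUMNS)]


def write_plot_table(table: pd.DataFrame, path: str | Path) -> None:
    table[list(PLOT_COLUMNS)].to_csv(path, index=False)


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end pipeline run."""

    input: str | None = None  # plot-table CSV; may be None if a table is passed directly
    stage: str = "flowering"  # free-text stage label (e.g. grain_filling)
    dialect: str = "as_printed"
    pc_tau: float = 0.53
    rf_tau: float = 1.9
    combine: str = "union"  # subset fed to RFE
    base_models: tuple[str, ...] = ("cubist", "rnn")
    model_params: dict = dataclasses.field(default_factory=dict)  # family -> params
    k: int = 10
    rfe_patience: int = 10
    rfe_cv_folds: int = 10
    forest_trees: int = 500
    seed: int = 0
    outdir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, table: pd.DataFrame | None = None) -> dict:
    """Execute the full workflow and return (and optionally write) the report."""
    if table is None:
        if config.input is None:
            raise ValueError("RunConfig.input is unset and no table was passed")
        logger.info("stage: reading plot table")
        table = read_plot_table(config.input)
    y = table["yield_t_ha"].to_numpy(dtype=float)

    logger.info("stage: computing vegetation indices")
    vit = compute_all(table, dialect=config.dialect)

    logger.info("stage: ranking features (PC, RF)")
    pc = pearson_ranking(vit, y)
    rf = rf_ranking(
        vit, y, forest_config=ForestConfig(n_trees=config.forest_trees), seed=config.seed
    )
    sub_pc = apply_threshold(pc, config.pc_tau)
    sub_rf = apply_threshold(rf, config.rf_tau)

    logger.info("stage: combining subsets")
    union = combine_subsets(sub_pc, sub_rf, "union")
    inter = combine_subsets(sub_pc, sub_rf, "intersection")
    start = union if config.combine == "union" else inter

    all_features = FeatureSubset.create(list_indices(), [{"step": "all_features"}])
    subsets: dict[str, FeatureSubset] = {
        "all_features": all_features,
        "pc": sub_pc,
        "rf": sub_rf,
        "union": union,
        "intersection": inter,
    }

    rfe_subsets: dict[str, FeatureSubset] = {}
    for family in config.base_models:
        logger.info("stage: recursive feature elimination (%s)", family)
        spec = ModelSpec(family, dict(config.model_params.get(family, {})), config.seed)
        rfe_cfg = RFEConfig(
            model_spec=spec,
            patience=config.rfe_patience,
            cv_folds=config.rfe_cv_folds,
            seed=config.seed,
        )
        rfe_subsets[family] = rfe_select(vit, y, start, rfe_cfg)

    logger.info("stage: cross-validated evaluation")
    results: dict[str, dict] = {}
    for family in config.base_models:
        spec = ModelSpec(family, dict(config.model_params.get(family, {})), config.seed)
        grid = dict(subsets)
        grid["pcrf_rfe"] = rfe_subsets[family]
        results[family] = {}
        for sub_name, sub in grid.items():
            cv = kfold_cv(vit, y, sub.names, spec, k=config.k, seed=config.seed)
            results[family][sub_name] = {
                "n_features": len(sub),
                "mean_r2": cv.mean_r2,
                "mean_rmse": cv.mean_rmse,
                "fold_r2": cv.fold_r2,
                "fold_rmse": cv.fold_rmse,
            }

    report = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stage": config.stage,
        "seed": config.seed,
        "n_plots": int(len(table)),
        "rankings": {"PC": pc.to_json(), "RF": rf.to_json()},
        "subsets": {
            name: list(sub.names)
            for name, sub in {**subsets, **{f"pcrf_rfe_{f}": s for f, s in rfe_subsets.items()}}.items()
        },
        "results": results,
    }
    if config.outdir is not None:
        _write_report(report, Path(config.outdir), config.stage)
    logger.info("stage: done")
    return report


def _write_report(report: dict, outdir: Path, stage: str) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / f"report_{stage}.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    rows = []
    for family, per_subset in report["results"].items():
        for sub_name, cell in per_subset.items():
            rows.append(
                {
                    "stage": stage,
                    "model": family,
                    "subset": sub_name,
                    "n_features": cell["n_features"],
                    "mean_r2": cell["mean_r2"],
                    "mean_rmse": cell["mean_rmse"],
                }
            )
    pd.DataFrame(rows).to_csv(outdir / f"summary_{stage}.csv", index=False)
    with open(outdir / f"summary_{stage}.txt", "w") as fh:
        fh.write(format_summary(report))


def format_summary(report: dict) -> str:
    """Plain-text model × subset accuracy grid for one stage."""
    lines = [
        f"stage: {report['stage']}   plots: {report['n_plots']}   "
        f"version: {report['package_version']}   config: {report['config_hash']}",
        f"{'model':8s} {'subset':14s} {'p':>3s} {'R2':>8s} {'RMSE':>8s}",
    ]
    for family, per_subset in report["results"].items():
        for sub_name, cell in per_subset.items():
            lines.append(
                f"{family:8s} {sub_name:14s} {cell['n_features']:3d} "
                f"{cell['mean_r2']:8.3f} {cell['mean_rmse']:8.3f}"
            )
    return "\n".join(lines) + "\n"
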