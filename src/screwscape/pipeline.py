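"""End-to-end study pipeline on the synthetic oracle.

Reproduces the study design: Latin-Hypercube training designs of increasing
size (plus their concatenation), dataset generation with true collision
labels, collision-classifier and strain-regressor training with replicate
ensembles, held-out evaluation tables (best and mean-of-replicates), a
reduced full-factorial exploration with the classifier gating the 16-input
regressor, per-screw strain-variation heatmaps, and a strain-range
comparison between the training designs and the full factorial.

Every stage is seeded from the run seed, and a JSON manifest records seeds,
counts, output files and their hashes so a run is exactly reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .ann import (
    CLASSIFIER_LAYERS,
    REGRESSOR14_LAYERS,
    REGRESSOR16_LAYERS,
    TrainConfig,
    ensemble_summary,
    forward,
    predict_label,
    select_best,
    strain14_features,
    strain16_features,
    train_replicates,
)
from .design import (
    FULLFACT_GRID,
    TRAINING_GRID,
    DesignGrid,
    full_factorial,
    lhs_design,
    split_dataset,
)
from .geometry import ANGLE_COLUMNS, PlateGeometry, default_geometry
from .oracle import OracleParams, default_params, generate_dataset
from .stats import (
    HeatmapAccumulator,
    classification_table,
    regression_metrics,
    strain_range_comparison,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("screwscape")


@dataclass
class RunConfig:
    """Settings of one pipeline run (defaults mirror the full study design)."""

    out_dir: str = "screwscape_run"
    seed: int = 0
    geometry: PlateGeometry | None = None
    oracle_params: OracleParams | None = None
    training_sizes: tuple[int, ...] = (500, 2000, 5000)
    test_size: int = 500
    n_replicates: int = 100
    outputs: tuple[str, ...] = ("e50_all", "e90_all")
    training_grid: DesignGrid = field(default_factory=lambda: TRAINING_GRID)
    fullfact_grid: DesignGrid = field(default_factory=lambda: FULLFACT_GRID)
    heatmap_alpha: float = 0.001
    range_alpha: float = 0.05
    fullfact_batch: int = 200_000
    max_epochs_classifier: int = 150
    max_epochs_regressor: int = 150
    run_fullfact: bool = True


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _angles(df: pd.DataFrame) -> np.ndarray:
    return df[list(ANGLE_COLUMNS)].to_numpy(dtype=float)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full study; returns (and writes) the run manifest."""
    t_start = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(cfg.seed)
    geometry = cfg.geometry or default_geometry()
    params = cfg.oracle_params or default_params(seed=rng_seed)
    sio.save_geometry(geometry, out / "geometry.json")
    sio.save_oracle_params(params, out / "oracle_params.json")
    manifest: dict = {
        "seed": rng_seed,
        "stages": {},
        "files": {},
        "versions": {"model_format": sio.MODEL_FORMAT_VERSION},
    }

    def record(name: str, path: Path):
        manifest["files"][name] = {
            "path": str(path.relative_to(out)),
            "sha256": _sha256(path),
        }

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"][name] = {"t": time.time() - t_start}

    # ---- designs + datasets -------------------------------------------
    stage("design")
    datasets: dict[str, pd.DataFrame] = {}
    start_index = 0
    for i, size in enumerate(cfg.training_sizes):
        design = lhs_design(size, cfg.training_grid, seed=rng_seed + 17 * (i + 1))
        data = generate_dataset(design, geometry, params, start_index=start_index)
        start_index += size
        name = f"train_{size}"
        datasets[name] = data
        sio.write_dataset(data, out / f"{name}.csv")
        record(name, out / f"{name}.csv")
    total = pd.concat(datasets.values(), ignore_index=True)
    name_total = f"train_{sum(cfg.training_sizes)}"
    datasets[name_total] = total
    sio.write_dataset(total, out / f"{name_total}.csv")
    record(name_total, out / f"{name_total}.csv")

    test_design = lhs_design(cfg.test_size, cfg.training_grid, seed=rng_seed + 9001)
    test_data = generate_dataset(
        test_design, geometry, params, start_index=start_index
    )
    start_index += cfg.test_size
    sio.write_dataset(test_data, out / "test.csv")
    record("test", out / "test.csv")
    # surviving (collision-free) bookkeeping, mirroring FE attrition
    manifest["stages"]["design"]["successful"] = {
        name: int((1 - d["collision"]).sum()) for name, d in datasets.items()
    }
    manifest["stages"]["design"]["successful"]["test"] = int(
        (1 - test_data["collision"]).sum()
    )

    # ---- training + evaluation ----------------------------------------
    stage("train")
    X_test_angles = _angles(test_data)
    y_test_flag = test_data["collision"].to_numpy()
    report: dict = {"classifier": {}, "strain16": {}, "strain14": {}}
    models: dict[str, object] = {}
    for name, data in datasets.items():
        tr, va, te = split_dataset(data, seed=rng_seed + 31)
        cls_cfg = TrainConfig(
            algorithm="lm", max_epochs=cfg.max_epochs_classifier, val_patience=10
        )
        ens = train_replicates(
            _angles(tr),
            tr["collision"].to_numpy(dtype=float),
            CLASSIFIER_LAYERS,
            cls_cfg,
            X_test_angles,
            y_test_flag,
            n_replicates=cfg.n_replicates,
            base_seed=rng_seed + 53,
            role="classifier",
            X_val=_angles(va),
            y_val=va["collision"].to_numpy(dtype=float),
        )
        summ = ensemble_summary(ens)
        best = select_best(ens)
        pct_true, pct_err = classification_table(
            y_test_flag, predict_label(best, X_test_angles)
        )
        report["classifier"][name] = {
            "pct_true_best": pct_true,
            "pct_error_best": pct_err,
            "pct_true_mean": summ["mean"],
            "pct_error_mean": 100.0 - summ["mean"],
        }
        models[f"collision_{name}"] = best

        reg_cfg = TrainConfig(algorithm="bayes", max_epochs=cfg.max_epochs_regressor)
        for key in cfg.outputs:
            for role_name, layers, feat in (
                ("strain16", REGRESSOR16_LAYERS, "with_flag"),
                ("strain14", REGRESSOR14_LAYERS, "angles_only"),
            ):
                if role_name == "strain14" and name != name_total:
                    continue  # the 14-input variant is reported for the largest set
                if feat == "with_flag":
                    Xtr = strain16_features(_angles(tr), tr["collision"].to_numpy())
                    Xva = strain16_features(_angles(va), va["collision"].to_numpy())
                    Xte = strain16_features(X_test_angles, y_test_flag)
                else:
                    Xtr, Xva, Xte = (
                        strain14_features(_angles(tr)),
                        strain14_features(_angles(va)),
                        strain14_features(X_test_angles),
                    )
                ens = train_replicates(
                    Xtr,
                    tr[key].to_numpy(),
                    layers,
                    reg_cfg,
                    Xte,
                    test_data[key].to_numpy(),
                    n_replicates=cfg.n_replicates,
                    base_seed=rng_seed + 71,
                    role="regressor",
                    X_val=Xva,
                    y_val=va[key].to_numpy(),
                )
                best = select_best(ens)
                pred = forward(best, Xte)
                m = regression_metrics(test_data[key].to_numpy(), pred)
                summ = ensemble_summary(ens)
                report[role_name].setdefault(name, {})[key] = {
                    "r2": m.r2,
                    "slope": m.slope,
                    "rmse_ustrain": m.rmse_ustrain,
                    "rmse_pct": m.rmse_pct,
                    "rmse_mean_ustrain": summ["mean"],
                }
                models[f"{role_name}_{key}_{name}"] = best

    sio.save_model_bundle(models, out / "models")
    record("models", out / "models" / "bundle.json")
    (out / "evaluation.json").write_text(json.dumps(report, indent=2))
    record("evaluation", out / "evaluation.json")

    # ---- full factorial + heatmaps + ranges ---------------------------
    if cfg.run_fullfact:
        stage("fullfact")
        classifier = models[f"collision_{name_total}"]
        heatmaps: dict[str, HeatmapAccumulator] = {
            key: HeatmapAccumulator(cfg.fullfact_grid) for key in cfg.outputs
        }
        ff_values: dict[str, list[np.ndarray]] = {key: [] for key in cfg.outputs}
        regs = {key: models[f"strain16_{key}_{name_total}"] for key in cfg.outputs}
        for batch in full_factorial(cfg.fullfact_grid, cfg.fullfact_batch):
            flags = predict_label(classifier, batch)
            keep = flags == 0
            feats = strain16_features(batch, flags)
            for key in cfg.outputs:
                vals = forward(regs[key], feats)
                heatmaps[key].update(batch, vals, keep)
                if np.any(keep):
                    ff_values[key].append(vals[keep])
        heat_frames = {}
        for key in cfg.outputs:
            frame = heatmaps[key].frame(alpha=cfg.heatmap_alpha)
            frame.to_csv(out / f"heatmap_{key}.csv", index=False)
            record(f"heatmap_{key}", out / f"heatmap_{key}.csv")
            heat_frames[key] = frame

        stage("ranges")
        ranges = {}
        for key in cfg.outputs:
            ff = pd.DataFrame({key: np.concatenate(ff_values[key])})
            named = {"full_factorial": ff}
            for name, d in datasets.items():
                named[name] = d.loc[d["collision"] == 0, [key]]
            comp = strain_range_comparison(
                named, key, reference="full_factorial", alpha=cfg.range_alpha
            )
            comp.to_csv(out / f"ranges_{key}.csv", index=False)
            record(f"ranges_{key}", out / f"ranges_{key}.csv")
            ranges[key] = comp.to_dict(orient="records")

    manifest["runtime_s"] = time.time() - t_start
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
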