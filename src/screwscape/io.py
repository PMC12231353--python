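"""Readers and writers for the package's file formats.

All formats are plain text: geometry and oracle parameters as JSON, designs
and datasets as headered CSV (angles as integers in degrees, strains as
floating microstrain), trained models as versioned JSON bundles.  Every
reader validates the schema and names the offending column on failure, and
``read(write(x))`` round-trips exactly for each format.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .ann import MLPModel
from .geometry import (
    ANGLE_COLUMNS,
    HeadSphere,
    PlateGeometry,
    ScrewAnchor,
)
from .oracle import DATASET_COLUMNS, OracleParams

__all__ = [
    "save_geometry",
    "load_geometry",
    "save_oracle_params",
    "load_oracle_params",
    "write_design",
    "read_design",
    "write_dataset",
    "read_dataset",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
    "save_model_bundle",
    "load_model_bundle",
]

MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# geometry JSON


def save_geometry(geometry: PlateGeometry, path: str | Path) -> None:
    doc = {
        "sphere": {
            "center": list(geometry.sphere.center),
            "radius_mm": geometry.sphere.radius,
        },
        "tjd_mm": geometry.tjd,
        "screws": [
            {
                "id": sid,
                "head": list(a.head_point),
                "neutral_axis": list(a.neutral_axis),
                "u_dp": list(a.u_dp),
                "u_ap": list(a.u_ap),
                "radius_mm": a.radius,
            }
            for sid, a in sorted(geometry.anchors.items())
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_geometry(path: str | Path) -> PlateGeometry:
    doc = json.loads(Path(path).read_text())
    try:
        sphere = HeadSphere(doc["sphere"]["center"], doc["sphere"]["radius_mm"])
        anchors = {
            int(s["id"]): ScrewAnchor(
                int(s["id"]),
                s["head"],
                s["neutral_axis"],
                s["u_dp"],
                s["u_ap"],
                float(s.get("radius_mm", 1.5)),
            )
            for s in doc["screws"]
        }
        return PlateGeometry(anchors, sphere, float(doc.get("tjd_mm", 8.0)))
    except KeyError as err:
        raise ValueError(f"geometry file {path} is missing field {err}") from err


# ---------------------------------------------------------------------------
# oracle parameter JSON


def save_oracle_params(params: OracleParams, path: str | Path) -> None:
    doc = {
        "baseline_strain": {str(k): v for k, v in params.baseline_strain.items()},
        "gamma": {str(k): v for k, v in params.gamma.items()},
        "self_coef": {str(k): list(v) for k, v in params.self_coef.items()},
        "cross_coef": {f"{t},{s}": list(v) for (t, s), v in params.cross_coef.items()},
        "calcar_gain": params.calcar_gain,
        "collision_inflation": params.collision_inflation,
        "noise_cv": params.noise_cv,
        "modulus_scale_exponent": params.modulus_scale_exponent,
        "rho_app": {str(k): v for k, v in params.rho_app.items()},
        "rho_ref": params.rho_ref,
        "seed": params.seed,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_oracle_params(path: str | Path) -> OracleParams:
    doc = json.loads(Path(path).read_text())
    try:
        return OracleParams(
            baseline_strain={int(k): float(v) for k, v in doc["baseline_strain"].items()},
            gamma={int(k): float(v) for k, v in doc["gamma"].items()},
            self_coef={int(k): tuple(v) for k, v in doc["self_coef"].items()},
            cross_coef={
                tuple(int(x) for x in k.split(",")): tuple(v)
                for k, v in doc["cross_coef"].items()
            },
            calcar_gain=float(doc["calcar_gain"]),
            collision_inflation=float(doc["collision_inflation"]),
            noise_cv=float(doc["noise_cv"]),
            modulus_scale_exponent=float(doc["modulus_scale_exponent"]),
            rho_app={int(k): float(v) for k, v in doc["rho_app"].items()},
            rho_ref=float(doc["rho_ref"]),
            seed=int(doc["seed"]),
        )
    except KeyError as err:
        raise ValueError(f"oracle params file {path} is missing field {err}") from err


# ---------------------------------------------------------------------------
# design / dataset CSV


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in ANGLE_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design lacks angle columns {missing}")
    out = design[list(ANGLE_COLUMNS)].astype(int)
    out.to_csv(path, index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ANGLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"design file {path} lacks columns {missing}")
    return df[list(ANGLE_COLUMNS)].astype(float)


def write_dataset(dataset: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in DATASET_COLUMNS if c not in dataset.columns]
    if missing:
        raise ValueError(f"dataset lacks columns {missing}")
    out = dataset[list(DATASET_COLUMNS)].copy()
    for c in ANGLE_COLUMNS:
        out[c] = out[c].astype(int)
    out["collision"] = out["collision"].astype(int)
    out.to_csv(path, index=False, float_format="%.6g")


def read_dataset(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset file {path} lacks columns {missing}")
    df = df[list(DATASET_COLUMNS)].copy()
    for c in ANGLE_COLUMNS:
        df[c] = df[c].astype(float)
    return df


# ---------------------------------------------------------------------------
# model JSON


def model_to_dict(model: MLPModel) -> dict:
    return {
        "format_version": MODEL_FORMAT_VERSION,
        "layer_sizes": list(model.layer_sizes),
        "role": model.role,
        "weights": [w.tolist() for w in model.weights],  # row-major
        "biases": [b.tolist() for b in model.biases],
        "input_min": None if model.input_min is None else model.input_min.tolist(),
        "input_max": None if model.input_max is None else model.input_max.tolist(),
        "output_min": model.output_min,
        "output_max": model.output_max,
        "metadata": {
            k: v for k, v in model.metadata.items() if isinstance(v, (int, float, str, bool, type(None)))
        },
    }


def model_from_dict(doc: Mapping) -> MLPModel:
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {doc.get('format_version')!r}"
        )
    return MLPModel(
        layer_sizes=tuple(doc["layer_sizes"]),
        weights=[np.asarray(w, dtype=float) for w in doc["weights"]],
        biases=[np.asarray(b, dtype=float) for b in doc["biases"]],
        role=doc["role"],
        input_min=None if doc["input_min"] is None else np.asarray(doc["input_min"]),
        input_max=None if doc["input_max"] is None else np.asarray(doc["input_max"]),
        output_min=doc["output_min"],
        output_max=doc["output_max"],
        metadata=dict(doc.get("metadata", {})),
    )


def save_model(model: MLPModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model)))


def load_model(path: str | Path) -> MLPModel:
    return model_from_dict(json.loads(Path(path).read_text()))


def save_model_bundle(models: Mapping[str, MLPModel], directory: str | Path) -> None:
    """Write one JSON per named model plus an index file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = {}
    for name, model in models.items():
        fname = f"{name}.json"
        save_model(model, directory / fname)
        index[name] = fname
    (directory / "bundle.json").write_text(
        json.dumps({"format_version": MODEL_FORMAT_VERSION, "models": index}, indent=2)
    )


def load_model_bundle(directory: str | Path) -> dict[str, MLPModel]:
    directory = Path(directory)
    doc = json.loads((directory / "bundle.json").read_text())
    return {
        name: load_model(directory / fname) for name, fname in doc["models"].items()
    }
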