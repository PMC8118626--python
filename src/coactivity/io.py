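"""Readers and writers for the shared on-disk formats.

Rasters travel as delimited text (neurons as rows, frames as columns, 0/1)
or as a compact ``.npz`` container; epoch annotations as JSON with 0-based,
half-open intervals; models as JSON with connections stored as sparse index
lists.  All JSON is written with sorted keys so identical objects produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .classifier import HiddenLayerClassifier
from .raster import Bout, Epoch, EpochAnnotation, as_raster


def write_raster(path, raster, delimiter: str = ",") -> None:
    np.savetxt(path, as_raster(raster), fmt="%d", delimiter=delimiter)


def read_raster(path, delimiter: str = ",") -> np.ndarray:
    try:
        a = np.loadtxt(path, delimiter=delimiter, dtype=np.int64, ndmin=2)
    except ValueError as e:
        raise ValueError(f"malformed raster file {path}: {e}") from e
    return as_raster(a)


def write_raster_npz(path, raster) -> None:
    np.savez_compressed(path, raster=as_raster(raster))


def read_raster_npz(path) -> np.ndarray:
    with np.load(path) as f:
        return as_raster(f["raster"])


def write_epochs(path, ann: EpochAnnotation) -> None:
    obj = {
        "epochs": [
            {"condition": e.condition, "start_frame": e.start, "end_frame_exclusive": e.end}
            for e in ann.epochs
        ],
        "bouts": [{"start_frame": b.start, "end_frame_exclusive": b.end} for b in ann.bouts],
    }
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_epochs(path) -> EpochAnnotation:
    try:
        obj = json.loads(Path(path).read_text())
        epochs = [
            Epoch(e["condition"], e["start_frame"], e["end_frame_exclusive"])
            for e in obj["epochs"]
        ]
        bouts = [Bout(b["start_frame"], b["end_frame_exclusive"]) for b in obj.get("bouts", [])]
    except (KeyError, TypeError, json.JSONDecodeError) as e:
        raise ValueError(f"malformed epoch file {path}: {e}") from e
    return EpochAnnotation(epochs=epochs, bouts=bouts)


def write_model(path, clf: HiddenLayerClassifier) -> None:
    obj = {
        "n_hidden": clf.n_hidden,
        "n_neurons": clf.n_neurons,
        "p_connect": clf.p_connect,
        "learning_rate": clf.learning_rate,
        "n_passes": clf.n_passes,
        "min_active_neurons": clf.min_active_neurons,
        "seed": clf.seed,
        "connections": [np.flatnonzero(row).tolist() for row in clf.connections],
        "weights": clf.weights.tolist(),
    }
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_model(path) -> HiddenLayerClassifier:
    try:
        obj = json.loads(Path(path).read_text())
        conn = np.zeros((obj["n_hidden"], obj["n_neurons"]), dtype=np.uint8)
        for i, idx in enumerate(obj["connections"]):
            conn[i, idx] = 1
        return HiddenLayerClassifier(
            connections=conn,
            weights=np.asarray(obj["weights"], dtype=np.float64),
            p_connect=obj["p_connect"],
            learning_rate=obj["learning_rate"],
            n_passes=obj["n_passes"],
            min_active_neurons=obj["min_active_neurons"],
            seed=obj["seed"],
        )
    except (KeyError, TypeError, json.JSONDecodeError) as e:
        raise ValueError(f"malformed model file {path}: {e}") from e


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
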