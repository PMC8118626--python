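"""End-to-end experiments: generate -> train -> test on surrogates.

The central comparison trains a classifier on a (real or synthetic) dataset,
then tests it on surrogate test sets that preserve behavior-specific
activity levels while either destroying (swap) or preserving (SHARC)
patterns of correlated activity.  The gap between the two surrogate
accuracies, normalized by the swap margin over chance,

    (Perf_SHARC - Perf_swap) / (Perf_swap - 0.5),

measures how much correlated activity adds to the information carried by
activity levels alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classifier import (
    FramePartition,
    alternating_blocks,
    build_network,
    evaluate,
    linear_baseline,
    train,
)
from .raster import EpochAnnotation, as_raster
from .surrogates import SharcParams, sharc_shuffle, swap_shuffle
from .synthetic import SyntheticStateConfig, two_state_dataset

log = logging.getLogger(__name__)

#: Datasets with fewer active neurons than this are flagged (not rejected).
MIN_ACTIVE_NEURONS_PER_DATASET = 25


@dataclass
class ExperimentConfig:
    """Fully serializable description of one experiment."""

    synthetic: dict = field(default_factory=dict)   # SyntheticStateConfig fields
    kind: str = "correlation"                       # correlation | rate | control
    p_connect: float = 0.3
    n_hidden: int = 1000
    n_passes: int = 500
    learning_rate: float = 0.05
    min_active_neurons: int = 3
    block: int = 500
    runs: int = 10
    sharc: dict = field(default_factory=dict)       # SharcParams fields (minus seed)
    linear_baselines: bool = False
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentConfig":
        return cls(**json.loads(text))


def shuffle_within_conditions(
    raster: np.ndarray,
    condition_slices: dict[str, slice],
    method: str = "swap",
    sharc_params: SharcParams | None = None,
    seed=None,
) -> np.ndarray:
    """Shuffle each condition's sub-raster independently, then reassemble.

    This preserves condition-specific activity levels; "swap" additionally
    destroys within-condition correlations while "sharc" preserves them
    (each sub-raster's own correlation matrix is the target).
    """
    raster = as_raster(raster)
    out = raster.copy()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    for sl in condition_slices.values():
        if method == "swap":
            out[:, sl] = swap_shuffle(raster[:, sl], "whole", seed=rng)
        elif method == "sharc":
            out[:, sl] = sharc_shuffle(raster[:, sl], params=sharc_params, seed=rng)
        else:
            raise ValueError(f"unknown shuffle method {method!r}")
    return out


def run_experiment(config: ExperimentConfig, outdir=None) -> dict:
    """Train on the original data; test on real, swap, and SHARC test sets.

    Returns a results bundle (plain dict, JSON-serializable) with per-run
    accuracies and the relative improvement of SHARC over swap.  All
    randomness fans out from ``config.seed``.
    """
    master = np.random.default_rng(config.seed)
    syn = SyntheticStateConfig(**{**config.synthetic, "seed": None})
    raster, labels, slices = two_state_dataset(syn, config.kind, master)
    if int((raster.sum(axis=1) > 0).sum()) < MIN_ACTIVE_NEURONS_PER_DATASET:
        log.warning("dataset has fewer than %d active neurons",
                    MIN_ACTIVE_NEURONS_PER_DATASET)
    partition = alternating_blocks(raster.shape[1], config.block)
    sharc_params = SharcParams(**config.sharc)

    acc_real, acc_swap, acc_sharc = [], [], []
    for _ in range(config.runs):
        clf = build_network(
            raster.shape[0], config.p_connect, config.n_hidden, master,
            learning_rate=config.learning_rate, n_passes=config.n_passes,
            min_active_neurons=config.min_active_neurons,
        )
        clf = train(clf, raster, labels, partition, master)
        acc_real.append(evaluate(clf, raster, labels, partition.test, master))
        swapped = shuffle_within_conditions(raster, slices, "swap", seed=master)
        acc_swap.append(evaluate(clf, swapped, labels, partition.test, master))
        sharced = shuffle_within_conditions(raster, slices, "sharc", sharc_params, master)
        acc_sharc.append(evaluate(clf, sharced, labels, partition.test, master))

    mean_swap = float(np.mean(acc_swap))
    mean_sharc = float(np.mean(acc_sharc))
    margin = mean_swap - 0.5
    rel = (mean_sharc - mean_swap) / margin if abs(margin) > 1e-9 else float("nan")
    bundle = {
        "config": asdict(config),
        "version": __version__,
        "accuracy_real": acc_real,
        "accuracy_swap_tested": acc_swap,
        "accuracy_sharc_tested": acc_sharc,
        "mean_accuracy_real": float(np.mean(acc_real)),
        "mean_accuracy_swap_tested": mean_swap,
        "mean_accuracy_sharc_tested": mean_sharc,
        "relative_improvement": rel,
    }
    if config.linear_baselines:
        bundle["accuracy_logistic"] = linear_baseline(
            raster, labels, partition, "logistic", config.min_active_neurons
        )
        bundle["accuracy_linear_svm"] = linear_baseline(
            raster, labels, partition, "linear-svm", config.min_active_neurons
        )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .io import write_json, write_raster

        write_raster(outdir / "raster.csv", raster)
        write_json(outdir / "results.json", bundle)
    return bundle
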